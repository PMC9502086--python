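"""Reference study conditions for the carrier analysis.

These constants describe the simulation campaign and analysis settings
the pipeline's defaults reproduce: the production-run inventory of the
c-state wild-type and mutant carrier systems, and the occupancy analysis
parameters (cutoff, window, threshold, frame spacing).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ProductionRun:
    system: str
    mutations: str
    n_replicas: int
    length_ns: float

    @property
    def total_ns(self) -> float:
        return self.n_replicas * self.length_ns


#: the production simulations of the study: three parallel 3-us runs of
#: the wild type, one 3-us run of E264A, and 200-ns runs of E264D/D167E
SIMULATION_CAMPAIGN: tuple[ProductionRun, ...] = (
    ProductionRun("wild-type", "/", 3, 3000.0),
    ProductionRun("E264A", "E264A", 1, 3000.0),
    ProductionRun("E264D", "E264D", 1, 200.0),
    ProductionRun("D167E", "D167E", 1, 200.0),
)


def total_simulation_time_us(campaign=SIMULATION_CAMPAIGN) -> float:
    """Total production simulation time in microseconds."""
    return sum(run.total_ns for run in campaign) / 1000.0


#: analysis defaults of the study
CONTACT_CUTOFF_NM = 0.33
OCCUPANCY_THRESHOLD_PCT = 25.0
ANALYSIS_WINDOW_PS = 2_000_000.0
FRAME_SPACING_PS = 10.0

#: number of human mitochondrial carriers, and how many enter the survey
#: after the stated exclusions
HUMAN_CARRIER_COUNT = 53
SURVEY_RETAINED_COUNT = 46
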