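"""Shared test utilities: independent oracles and fixture builders."""

import re

from loopscan.interactions import ContactPairSpec
from loopscan.motifs import DEFAULT_SMALL_RESIDUES


def regex_oracle(pattern: str, seq: str, small=DEFAULT_SMALL_RESIDUES) -> list[int]:
    """Independent overlapping-match finder via the re module."""
    parts = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            parts.append("[" + pattern[i + 1 : j] + "]")
            i = j + 1
        elif ch == "x":
            parts.append(".")
            i += 1
        elif ch == "π":
            parts.append("[" + small + "]")
            i += 1
        else:
            parts.append(ch)
            i += 1
    rx = re.compile("(?=(" + "".join(parts) + "))")
    return [m.start() + 1 for m in rx.finditer(seq)]


def pair_spec(resid_a=1, resid_b=2, **kw) -> ContactPairSpec:
    defaults = dict(
        residue_a=resid_a,
        resname_a="SER",
        atoms_a=("OG",),
        context_a="",
        residue_b=resid_b,
        resname_b="SER",
        atoms_b=("OG",),
        context_b="",
        kind="H-bond",
    )
    defaults.update(kw)
    return ContactPairSpec(**defaults)
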