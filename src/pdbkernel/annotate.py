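"""3-state secondary structure and relative solvent accessibility.

The 8-state secondary-structure alphabet is reduced to helix/strand/coil
with the conventional mapping (310 and pi helices count as helix, the
isolated beta bridge as strand, turns and bends as coil).  Relative
solvent accessibility (RSA) is the absolute accessible surface divided by
a residue-type maximum and is classed exposed (> 0.37), buried (< 0.069)
or intermediate, both breakpoints strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

from .pdb_io import ChainRecord

logger = logging.getLogger(__name__)

RSA_EXPOSED = 0.37
RSA_BURIED = 0.069

SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", " ": "C", "-": "C",
}

#: Maximum accessible surface area per residue type (Å²), Rost–Sander
#: normalization; override via the max_acc argument of compute_rsa.
MAX_ACC = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

#: backend row: (reference position, 8-state code, absolute accessibility)
SSBackend = Callable[[ChainRecord], Iterable[tuple[int, str, float]]]


@dataclass
class SSAnnotation:
    """Per-reference-position annotations; '-' marks positions without
    coordinates (hence without structural annotation)."""

    ss3: str
    rsa: list[float | None]
    rsa3: str

    def __post_init__(self):
        if not (len(self.ss3) == len(self.rsa) == len(self.rsa3)):
            raise ValueError("annotation tracks must share one length")


def ss8_to_ss3(ss8: str) -> str:
    """Reduce an 8-state secondary-structure string to H/E/C."""
    try:
        return "".join(SS8_TO_SS3[c] for c in ss8)
    except KeyError as exc:
        raise ValueError(f"unknown secondary-structure code {exc}") from None


def classify_rsa(rsa: float) -> str:
    """E above 0.37, B below 0.069, I in between (strict breakpoints)."""
    if rsa < 0:
        raise ValueError("RSA cannot be negative")
    if rsa > RSA_EXPOSED:
        return "E"
    if rsa < RSA_BURIED:
        return "B"
    return "I"


def compute_rsa(abs_acc: float, residue_type: str,
                max_acc: dict[str, float] | None = None) -> float:
    """Absolute accessibility over the residue-type maximum, clamped to
    [0, 1] (accessibility tables occasionally exceed the maximum)."""
    if abs_acc < 0:
        raise ValueError("absolute accessibility cannot be negative")
    table = max_acc or MAX_ACC
    letter = residue_type.upper()
    if letter not in table:
        raise ValueError(f"unknown residue type {residue_type!r}")
    rsa = abs_acc / table[letter]
    if rsa > 1.0:
        logger.warning("RSA %.3f > 1 for %s; clamped", rsa, residue_type)
        rsa = 1.0
    return rsa


def annotate_chain(chain: ChainRecord, ss_backend: SSBackend) -> SSAnnotation:
    """Assemble per-position 3-state annotations from a backend supplying
    8-state codes and absolute accessibilities keyed by reference
    position.  Positions without coordinates come out as '-'."""
    try:
        rows = list(ss_backend(chain))
    except Exception as exc:
        raise RuntimeError(f"secondary-structure backend failed: {exc}") from exc
    if not rows:
        raise ValueError("secondary-structure backend returned no rows")

    n = len(chain.ref_seq)
    ss3 = ["-"] * n
    rsa: list[float | None] = [None] * n
    rsa3 = ["-"] * n
    for pos, ss8, abs_acc in rows:
        if not 1 <= pos <= n:
            raise ValueError(f"backend position {pos} outside 1..{n}")
        ss3[pos - 1] = ss8_to_ss3(ss8)
        letter = chain.ref_seq[pos - 1]
        if letter in MAX_ACC:
            r = compute_rsa(abs_acc, letter)
            rsa[pos - 1] = r
            rsa3[pos - 1] = classify_rsa(r)
    return SSAnnotation(ss3="".join(ss3), rsa=rsa, rsa3="".join(rsa3))


def annotation_block(chain: ChainRecord, ann: SSAnnotation,
                     width: int = 60) -> str:
    """Three-line display block (sequence / secondary structure / RSA
    class) wrapped at the given width, as in a chain-detail view."""
    lines = []
    for start in range(0, len(chain.ref_seq), width):
        lines.append(chain.ref_seq[start:start + width])
        lines.append(ann.ss3[start:start + width])
        lines.append(ann.rsa3[start:start + width])
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
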