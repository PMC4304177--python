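"""Model selection for missing regions.

For each missing region of a cleaned chain a candidate backend proposes
full-coordinate models; candidates that disturb the experimental part are
discarded (rmsdRest, the RMSD over all residues outside the missing
regions, must stay within 0.1 Å — computed in the shared frame without
superposition, since superposing would hide exactly the drift the filter
exists to catch) and the lowest-energy survivor is kept.

The bundled stub generator places missing backbone atoms by linear
interpolation between the anchoring residues (linear extension at chain
termini) with seeded jitter on the modelled atoms only.  It makes no claim
of physical realism; it exists so the selection protocol is exercisable
without an external modelling engine.  The energy backend contract is a
single number per candidate, lower is better; an external statistical
potential plugs into the same slot.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .pdb_io import AA_1TO3, AtomRecord, ChainRecord, ResidueRecord

#: modelled regions at least this long are flagged low-confidence
LOW_CONFIDENCE_LENGTH = 7

EnergyScorer = Callable[[ChainRecord], float]


class NoModelError(RuntimeError):
    """No candidate survived the rmsdRest filter for a region."""

    def __init__(self, region: tuple[int, int], n_generated: int):
        super().__init__(
            f"no model for region {region}: all {n_generated} candidates "
            f"exceeded the rmsdRest bound")
        self.region = region
        self.n_generated = n_generated


@dataclass
class LoopTask:
    chain: ChainRecord
    missing_regions: list[tuple[int, int]]
    n_candidates: int = 500
    rmsd_rest_max: float = 0.1

    def __post_init__(self):
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.rmsd_rest_max <= 0:
            raise ValueError("rmsd_rest_max must be positive")
        if not self.missing_regions:
            raise ValueError("nothing to model: no missing regions")


@dataclass
class LoopCandidate:
    chain: ChainRecord
    rmsd_rest: float = math.nan
    energy: float = math.nan


@dataclass
class RegionReport:
    region: tuple[int, int]
    length: int
    n_generated: int
    n_after_filter: int
    selected_energy: float
    low_confidence: bool
    terminal: bool = False


def _in_regions(pos: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in regions)


def rmsd_rest(candidate: ChainRecord, original: ChainRecord,
              missing_regions: Sequence[tuple[int, int]]) -> float:
    """RMSD over all heavy atoms of residues outside the missing regions,
    in the shared coordinate frame (no superposition)."""
    cand = {r.seq_num: r for r in candidate.residues}
    sq_sum = 0.0
    n = 0
    for res in original.residues:
        if _in_regions(res.seq_num, missing_regions):
            continue
        other = cand.get(res.seq_num)
        if other is None:
            raise ValueError(f"candidate lacks non-loop residue {res.seq_num}")
        theirs = {a.name: a for a in other.atoms}
        if set(theirs) != {a.name for a in res.atoms}:
            raise ValueError(
                f"atom-set mismatch on non-loop residue {res.seq_num}")
        for atom in res.atoms:
            d = np.subtract(atom.coords, theirs[atom.name].coords)
            sq_sum += float(d @ d)
            n += 1
    if n == 0:
        raise ValueError("no non-loop atoms to compare")
    return math.sqrt(sq_sum / n)


def filter_candidates(cands: Iterable[LoopCandidate], task: LoopTask
                      ) -> list[LoopCandidate]:
    """Drop candidates whose rmsdRest strictly exceeds the bound (a value
    exactly at the bound survives); order preserved."""
    return [c for c in cands if c.rmsd_rest <= task.rmsd_rest_max]


def select_model(cands: Sequence[LoopCandidate]) -> LoopCandidate:
    """Lowest energy wins; ties go to the earliest-generated candidate."""
    if not cands:
        raise NoModelError((0, 0), 0)
    return min(cands, key=lambda c: c.energy)


class StubGenerator:
    """Deterministic geometric placeholder for a modelling engine.

    Non-loop coordinates are copied verbatim (so rmsdRest is exactly zero
    for them); each missing residue gets backbone N/CA/C/O atoms on the
    straight segment joining the anchor CA positions, jittered by a seeded
    normal perturbation whose scale varies per candidate.
    """

    BACKBONE_OFFSETS = {
        "N": (-0.5, 0.3, 0.0), "CA": (0.0, 0.0, 0.0),
        "C": (0.5, 0.3, 0.0), "O": (0.6, 1.2, 0.0),
    }

    def __init__(self, seed: int = 0, jitter: float = 0.25):
        self.seed = seed
        self.jitter = jitter

    def generate(self, chain: ChainRecord, region: tuple[int, int],
                 n: int) -> list[ChainRecord]:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, region[0], region[1]]))
        return [self._one(chain, region, rng, i) for i in range(n)]

    def _anchors(self, chain: ChainRecord, region: tuple[int, int]
                 ) -> tuple[np.ndarray, np.ndarray]:
        s, e = region
        by_num = {r.seq_num: r for r in chain.residues}
        length = e - s + 1

        def ca(num: int) -> np.ndarray | None:
            res = by_num.get(num)
            if res is None:
                return None
            for a in res.atoms:
                if a.name == "CA":
                    return np.asarray(a.coords)
            return None

        left, right = ca(s - 1), ca(e + 1)
        step = np.array([3.8, 0.0, 0.0])
        if left is None and right is None:
            left = np.zeros(3)
            right = left + step * (length + 1)
        elif left is None:  # N-terminal extension
            left = right - step * (length + 1)
        elif right is None:  # C-terminal extension
            right = left + step * (length + 1)
        return left, right

    def _one(self, chain: ChainRecord, region: tuple[int, int],
             rng: np.random.Generator, index: int) -> ChainRecord:
        s, e = region
        left, right = self._anchors(chain, region)
        length = e - s + 1
        out = copy.deepcopy(chain)
        scale = self.jitter * (0.2 + rng.random())
        new_residues = []
        for k, pos in enumerate(range(s, e + 1), start=1):
            frac = k / (length + 1)
            base = left + frac * (right - left)
            letter = chain.ref_seq[pos - 1]
            res = ResidueRecord(AA_1TO3.get(letter, "UNK"), pos)
            for name, off in self.BACKBONE_OFFSETS.items():
                coords = base + np.asarray(off) + rng.normal(0, scale, 3)
                res.atoms.append(AtomRecord(
                    name=name, element=name[0],
                    coords=tuple(round(float(c), 3) for c in coords)))
            new_residues.append(res)
        out.residues = sorted(out.residues + new_residues,
                              key=lambda r: r.seq_num)
        return out


def stub_energy(chain: ChainRecord) -> float:
    """Deterministic pseudo-energy: summed squared consecutive-CA
    distances (a compactness proxy; lower is better).  Stands behind the
    same contract an external statistical potential would."""
    cas = [np.asarray(a.coords)
           for r in sorted(chain.residues, key=lambda r: r.seq_num)
           for a in r.atoms if a.name == "CA"]
    if len(cas) < 2:
        return 0.0
    diffs = np.diff(np.stack(cas), axis=0)
    return float((diffs ** 2).sum())


@dataclass
class FillReport:
    regions: list[RegionReport] = field(default_factory=list)


def fill_chain(task: LoopTask, generator: StubGenerator | None = None,
               scorer: EnergyScorer | None = None
               ) -> tuple[ChainRecord, FillReport]:
    """Model every missing region: generate candidates, filter on
    rmsdRest against the experimental structure, select the lowest-energy
    survivor, and splice it into the working chain.

    The candidate budget applies per region.  Regions of length >= 7 and
    all terminal regions are flagged low-confidence.
    """
    generator = generator or StubGenerator()
    scorer = scorer or stub_energy
    original = task.chain
    ref_len = len(original.ref_seq)
    working = copy.deepcopy(original)
    report = FillReport()

    for region in sorted(task.missing_regions):
        raw = generator.generate(working, region, task.n_candidates)
        cands = [
            LoopCandidate(chain=c,
                          rmsd_rest=rmsd_rest(c, original,
                                              task.missing_regions))
            for c in raw
        ]
        survivors = filter_candidates(cands, task)
        if not survivors:
            raise NoModelError(region, len(cands))
        for c in survivors:
            c.energy = scorer(c.chain)
        chosen = select_model(survivors)
        working = chosen.chain
        length = region[1] - region[0] + 1
        terminal = region[0] == 1 or region[1] == ref_len
        report.regions.append(RegionReport(
            region=region, length=length, n_generated=len(cands),
            n_after_filter=len(survivors), selected_energy=chosen.energy,
            low_confidence=length >= LOW_CONFIDENCE_LENGTH or terminal,
            terminal=terminal,
        ))

    covered = {r.seq_num for r in working.residues}
    if covered != set(range(1, ref_len + 1)):
        raise RuntimeError("filled chain does not cover the reference")
    return working, report
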