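"""Synthetic legacy-PDB files and scripted search backends with known
ground truth.

Chain fixtures embody a requested set of defects (missing regions,
modified residues, alternate conformations, extra atoms, CA-only traces,
unknown residues) on an idealized backbone laid out along a line — no
module under test depends on realistic folding, only on the bookkeeping
the cleaning rules inspect.  Family fixtures plant a similarity structure
for the clustering module, and hit scripts drive the domain-assignment
protocol.  Every fixture carries the ground truth it was built from.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .domain_assign import Query, SearchHit
from .pdb_io import AA_1TO3
from .redundancy import PriorityKey, pairwise_similarity

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: modified-code -> standard-code pairs available to fixture MODRES records
MODIFIED_CODES = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "MLY": "LYS", "HYP": "PRO",
}
_STD_TO_MOD = {v: k for k, v in MODIFIED_CODES.items()}


class FixtureSpecError(ValueError):
    """The requested defects are inconsistent with the sequence."""


class AmbiguousFixtureError(FixtureSpecError):
    """The planted missing regions are not the leftmost optimal threading,
    so cleaning could legitimately report different regions."""


@dataclass
class DefectSpec:
    missing_regions: list[tuple[int, int]] = field(default_factory=list)
    modres: list[tuple[int, str, str]] = field(default_factory=list)
    altloc_atoms: list[tuple[int, str, int]] = field(default_factory=list)
    extra_atoms: list[tuple[int, str]] = field(default_factory=list)
    ca_only: bool = False
    x_positions: list[int] = field(default_factory=list)


@dataclass
class ChainGroundTruth:
    """What cleaning must report for the fixture."""

    ref_seq: str
    coord_positions: list[int]
    missing_regions: list[tuple[int, int]]
    restored_positions: list[int]
    n_atoms_pruned: int
    reasons: list[str]
    kept: bool
    coords: dict[tuple[int, str], tuple[float, float, float]]


def _leftmost_threading(ref: str, coord: str) -> list[int] | None:
    """Greedy leftmost full-match threading of coord into ref (1-based
    positions), or None when no full-match threading exists.  Independent
    of the cleaning module's aligner."""
    out: list[int] = []
    i = 0
    for c in coord:
        while i < len(ref) and ref[i] != c:
            i += 1
        if i == len(ref):
            return None
        out.append(i + 1)
        i += 1
    return out


def _regions_from_positions(positions: list[int], n: int
                            ) -> list[tuple[int, int]]:
    mapped = set(positions)
    regions = []
    start = None
    for p in range(1, n + 1):
        if p not in mapped:
            if start is None:
                start = p
        elif start is not None:
            regions.append((start, p - 1))
            start = None
    if start is not None:
        regions.append((start, n))
    return regions


_BACKBONE_OFFSETS = {
    "N": (-1.20, 0.50, 0.00), "CA": (0.00, 0.00, 0.00),
    "C": (1.20, 0.50, 0.00), "O": (1.30, 1.70, 0.00),
}


def make_chain_fixture(
    seq: str,
    defects: DefectSpec | None = None,
    seed: int = 0,
    pdb_id: str = "TEST",
    chain_id: str = "A",
    method: str = "XRAY",
    resolution: float | None = 2.00,
    deposit_date: _dt.date = _dt.date(2006, 12, 5),
) -> tuple[str, ChainGroundTruth]:
    """Emit a legacy-PDB file embodying exactly the requested defects and
    the ground truth cleaning must recover.

    Raises FixtureSpecError on inconsistent defects and
    AmbiguousFixtureError when the planted missing regions could not be
    the unique leftmost alignment outcome (re-randomize the sequence and
    retry in that case).
    """
    if not seq:
        raise FixtureSpecError("sequence must be non-empty")
    defects = defects or DefectSpec()
    n = len(seq)
    rng = np.random.default_rng(seed)

    missing = sorted(defects.missing_regions)
    for (s, e), later in zip(missing, missing[1:] + [(n + 1, n + 1)]):
        if not 1 <= s <= e <= n:
            raise FixtureSpecError(f"region ({s},{e}) outside 1..{n}")
        if e >= later[0]:
            raise FixtureSpecError("missing regions must be disjoint")
    missing_set = {p for s, e in missing for p in range(s, e + 1)}

    x_set = set(defects.x_positions)
    if not x_set <= set(range(1, n + 1)):
        raise FixtureSpecError("x_positions outside sequence")

    modres_at: dict[int, tuple[str, str]] = {}
    for pos, mod, std in defects.modres:
        if pos in missing_set or pos in x_set:
            raise FixtureSpecError(f"MODRES position {pos} has no residue")
        expected_std = AA_1TO3.get(seq[pos - 1])
        if std != expected_std:
            raise FixtureSpecError(
                f"MODRES standard code {std} contradicts sequence letter "
                f"{seq[pos - 1]} at {pos}")
        modres_at[pos] = (mod, std)

    for pos, name, k in defects.altloc_atoms:
        if pos in missing_set or k < 2:
            raise FixtureSpecError(f"bad altloc spec at {pos}")
    for pos, name in defects.extra_atoms:
        if pos in missing_set:
            raise FixtureSpecError(f"extra atom at missing position {pos}")

    # reference sequence as cleaning will see it
    ref_seq = "".join("X" if (i + 1) in x_set else c
                      for i, c in enumerate(seq))
    coord_positions = [p for p in range(1, n + 1) if p not in missing_set]
    coord_seq = "".join(ref_seq[p - 1] for p in coord_positions)

    threading = _leftmost_threading(ref_seq, coord_seq)
    if threading != coord_positions:
        raise AmbiguousFixtureError(
            "planted missing regions are not the leftmost threading")

    # --- emit the file ---------------------------------------------------
    def three(pos: int) -> str:
        if pos in x_set:
            return "UNK"
        if pos in modres_at:
            return modres_at[pos][0]
        return AA_1TO3[seq[pos - 1]]

    mon = ["", "JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"][deposit_date.month]
    date_str = f"{deposit_date.day:02d}-{mon}-{deposit_date.year % 100:02d}"
    lines = [
        f"HEADER    {'SYNTHETIC PROTEIN':<40}{date_str:>9}   {pdb_id}",
        "EXPDTA    " + {"XRAY": "X-RAY DIFFRACTION",
                        "NMR": "SOLUTION NMR"}.get(method, "OTHER"),
    ]
    if method == "NMR":
        resolution = None
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    lines.append("SOURCE    SYNTHETIC FIXTURE")

    codes = [three(p) for p in range(1, n + 1)]
    for i, start in enumerate(range(0, n, 13), start=1):
        block = " ".join(f"{t:>3}" for t in codes[start:start + 13])
        lines.append(f"SEQRES {i:>3} {chain_id} {n:>4}  {block}")
    for pos, (mod, std) in sorted(modres_at.items()):
        lines.append(f"MODRES {pdb_id} {mod:>3} {chain_id} {pos:>4}  {std:>3}")

    altloc_at = {(p, a): k for p, a, k in defects.altloc_atoms}
    extra_at: dict[int, list[str]] = {}
    for pos, name in defects.extra_atoms:
        extra_at.setdefault(pos, []).append(name)

    truth_coords: dict[tuple[int, str], tuple[float, float, float]] = {}
    n_pruned = 0
    serial = 0
    atom_lines: list[str] = []

    def emit(rec: str, name: str, res3: str, pos: int,
             xyz: tuple[float, float, float], alt: str = " ",
             occ: float = 1.0) -> None:
        nonlocal serial
        serial += 1
        pad = f" {name:<3}" if len(name) < 4 else f"{name:<4}"
        atom_lines.append(
            f"{rec}{serial:>5} {pad}{alt}{res3:>3} {chain_id}{pos:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2}")

    for pos in coord_positions:
        res3 = three(pos)
        rec = "HETATM" if pos in modres_at else "ATOM  "
        base = np.array([3.8 * pos, 0.0, 0.0])
        names = ["CA"] if defects.ca_only else list(_BACKBONE_OFFSETS)
        for name in names:
            off = np.asarray(_BACKBONE_OFFSETS[name])
            xyz = tuple(round(float(v), 3)
                        for v in base + off + rng.normal(0, 0.05, 3))
            nv = altloc_at.get((pos, name), 0) if not defects.ca_only else 0
            if nv >= 2:
                emit(rec, name, res3, pos, xyz, alt="A", occ=0.5)
                for v in range(1, nv):
                    shifted = (xyz[0] + 0.5 * v, xyz[1], xyz[2])
                    emit(rec, name, res3, pos, shifted,
                         alt=chr(ord("A") + v), occ=0.5)
            else:
                emit(rec, name, res3, pos, xyz)
            truth_coords[(pos, name)] = xyz
        if not defects.ca_only:
            for name in extra_at.get(pos, ()):  # beyond standard composition
                xyz = tuple(round(float(v), 3)
                            for v in base + rng.normal(0, 0.5, 3) + 2.0)
                emit(rec, name, res3, pos, xyz)
                n_pruned += 1

    lines.extend(atom_lines)
    last = coord_positions[-1]
    lines.append(f"TER   {serial + 1:>5}      {three(last):>3} "
                 f"{chain_id}{last:>4}")
    lines.append("END")
    text = "\n".join(lines) + "\n"

    reasons = []
    if defects.ca_only:
        reasons.append("CA_ONLY")
    if n < 30:
        reasons.append("TOO_SHORT")
    if ref_seq.count("X") / n > 0.10:
        reasons.append("TOO_MANY_X")
    truth = ChainGroundTruth(
        ref_seq=ref_seq,
        coord_positions=coord_positions,
        missing_regions=missing,
        restored_positions=sorted(modres_at),
        n_atoms_pruned=n_pruned,
        reasons=reasons,
        kept=not reasons,
        coords=truth_coords,
    )
    return text, truth


def random_defect_fixture(rng: np.random.Generator,
                          min_len: int = 33, max_len: int = 80
                          ) -> tuple[str, ChainGroundTruth, DefectSpec]:
    """Draw a random sequence and DefectSpec, retrying until the planted
    regions are unambiguous; occasionally emits chains meant to be
    filtered out (too short, CA-only, X-heavy)."""
    for _ in range(200):
        kind = rng.random()
        if kind < 0.08:
            n = int(rng.integers(10, 30))  # too short
        else:
            n = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        defects = DefectSpec()
        if kind < 0.16 and kind >= 0.08:
            defects.ca_only = True
        if 0.16 <= kind < 0.24:
            k = max(1, int(0.2 * n))  # X-heavy
            defects.x_positions = sorted(
                int(p) + 1 for p in rng.choice(n, size=k, replace=False))
        # interior missing regions
        n_regions = int(rng.integers(0, 3)) if n >= 20 else 0
        taken: set[int] = set()
        for _r in range(n_regions):
            length = int(rng.integers(1, 7))
            start = int(rng.integers(2, n - length))
            span = set(range(start, start + length))
            pad = set(range(start - 1, start + length + 1))
            if pad & taken:
                continue
            defects.missing_regions.append((start, start + length - 1))
            taken |= span
        available = [p for p in range(1, n + 1)
                     if p not in taken
                     and p not in set(defects.x_positions)]
        if not defects.ca_only and available:
            if rng.random() < 0.5:
                pos = int(rng.choice(available))
                std = AA_1TO3[seq[pos - 1]]
                mod = _STD_TO_MOD.get(std)
                if mod:
                    defects.modres.append((pos, mod, std))
            if rng.random() < 0.5:
                pos = int(rng.choice(available))
                defects.altloc_atoms.append(
                    (pos, "CA", int(rng.integers(2, 4))))
            if rng.random() < 0.5:
                pos = int(rng.choice(available))
                defects.extra_atoms.append((pos, "ZX1"))
        try:
            text, truth = make_chain_fixture(
                seq, defects, seed=int(rng.integers(2 ** 31)))
        except AmbiguousFixtureError:
            continue
        return text, truth, defects
    raise RuntimeError("could not draw an unambiguous fixture")


# --- family fixtures -----------------------------------------------------


@dataclass
class FamilySpec:
    n_members: int
    base_length: int
    identity_matrix: list[list[float]]
    length_deltas: list[int] | None = None
    resolutions: list[float | None] | None = None
    methods: list[str] | None = None
    dates: list[_dt.date] | None = None


class InfeasibleFamilyError(ValueError):
    pass


@dataclass
class FamilyFixture:
    seqs: dict[str, str]
    keys: dict[str, PriorityKey]
    realized: dict[tuple[str, str], float]
    planted_groups: list[list[str]]
    fasta: str

    def expected_partition(self, level: float) -> list[list[str]]:
        """Independent greedy simulation over the realized similarity
        matrix (separate code path from the redundancy module)."""
        order = _oracle_priority_order(list(self.keys.values()))
        clusters: list[tuple[str, list[str]]] = []
        for key in order:
            cid = key.chain_id
            for rep, members in clusters:
                if self.realized[(rep, cid)] >= level:
                    members.append(cid)
                    break
            else:
                clusters.append((cid, [cid]))
        return [members for _, members in clusters]


def grouped_identity_matrix(group_sizes: list[int], within: float,
                            between: float) -> list[list[float]]:
    labels = [g for g, size in enumerate(group_sizes) for _ in range(size)]
    n = len(labels)
    return [[1.0 if i == j else (within if labels[i] == labels[j]
                                 else between)
             for j in range(n)] for i in range(n)]


def _oracle_priority_order(keys: list[PriorityKey]) -> list[PriorityKey]:
    """Insertion-sorted decreasing priority by a re-derivation of the
    pairwise rule (independent of redundancy.priority_sorted)."""

    def beats(a: PriorityKey, b: PriorityKey) -> bool:
        if abs(a.length - b.length) >= 10:
            return a.length > b.length

        def res(k: PriorityKey):
            if k.is_xray and k.resolution is not None:
                return (k.resolution, 0)
            return (float("inf"), 0 if k.is_xray else 1)

        if res(a) != res(b):
            return res(a) < res(b)
        da = a.deposit_date.toordinal() if a.deposit_date else 0
        db = b.deposit_date.toordinal() if b.deposit_date else 0
        if da != db:
            return da > db
        return a.chain_id < b.chain_id

    out: list[PriorityKey] = []
    for key in keys:
        i = len(out)
        while i > 0 and beats(key, out[i - 1]):
            i -= 1
        out.insert(i, key)
    return out


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    letters = list(seq)
    for i in range(len(letters)):
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(letters[i], "")
            letters[i] = choices[int(rng.integers(len(choices)))]
    return "".join(letters)


def make_family(spec: FamilySpec, seed: int = 0,
                tolerance: float = 0.03) -> FamilyFixture:
    """Generate member sequences realizing the target identity matrix.

    Each member is mutated from the already-generated member it should be
    most similar to, with a bisection on the substitution rate measured by
    the built-in aligner.  Parent-pair similarities must land within the
    tolerance of their targets or InfeasibleFamilyError is raised; the
    full realized matrix is recorded as ground truth.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_members
    if len(spec.identity_matrix) != n:
        raise InfeasibleFamilyError("identity matrix size mismatch")
    deltas = spec.length_deltas or [0] * n
    ids = [f"S{i:03d}_A" for i in range(n)]

    base = "".join(rng.choice(list(AMINO_ACIDS), size=spec.base_length))
    seqs: dict[str, str] = {}

    def resized(s: str, length: int) -> str:
        if len(s) >= length:
            return s[:length]
        tail = "".join(rng.choice(list(AMINO_ACIDS), size=length - len(s)))
        return s + tail

    for i in range(n):
        length = spec.base_length + deltas[i]
        if i == 0:
            seqs[ids[0]] = resized(base, length)
            continue
        parent_idx = max(range(i), key=lambda j: spec.identity_matrix[i][j])
        target = spec.identity_matrix[i][parent_idx]
        parent = seqs[ids[parent_idx]]
        template = resized(parent, length)
        best_seq, best_err = None, float("inf")
        lo, hi = 0.0, 1.0
        for _ in range(18):
            rate = (lo + hi) / 2
            cand = _mutate(template, rate, rng)
            sim = pairwise_similarity(parent, cand).value
            err = abs(sim - target)
            if err < best_err:
                best_seq, best_err = cand, err
            if best_err <= tolerance / 2:
                break
            if sim > target:
                lo = rate
            else:
                hi = rate
        if best_err > tolerance:
            raise InfeasibleFamilyError(
                f"could not realize identity {target:.2f} for member {i} "
                f"(best miss {best_err:.3f})")
        seqs[ids[i]] = best_seq

    realized = {}
    for a in ids:
        for b in ids:
            realized[(a, b)] = (1.0 if a == b
                                else pairwise_similarity(seqs[a], seqs[b]).value)

    resolutions = spec.resolutions or [2.0] * n
    methods = spec.methods or ["XRAY"] * n
    dates = spec.dates or [_dt.date(2010, 1, 1)] * n
    keys = {
        ids[i]: PriorityKey(
            chain_id=ids[i], length=len(seqs[ids[i]]),
            is_xray=methods[i] == "XRAY",
            resolution=resolutions[i] if methods[i] == "XRAY" else None,
            deposit_date=dates[i])
        for i in range(n)
    }

    # group labels recovered from the target matrix (>= 0.5 treated as
    # same-group for bookkeeping only)
    groups: list[list[str]] = []
    assigned: set[int] = set()
    for i in range(n):
        if i in assigned:
            continue
        group = [ids[i]]
        assigned.add(i)
        for j in range(i + 1, n):
            if j not in assigned and spec.identity_matrix[i][j] >= 0.5:
                group.append(ids[j])
                assigned.add(j)
        groups.append(group)

    fasta = "".join(f">{cid}\n{seqs[cid]}\n" for cid in ids)
    return FamilyFixture(seqs=seqs, keys=keys, realized=realized,
                         planted_groups=groups, fasta=fasta)


# --- scripted search backends --------------------------------------------


class ScriptedBackend:
    """Backend returning planted hits, clipped to the requested interval."""

    def __init__(self, hits: list[SearchHit]):
        self.hits = hits

    def search(self, query: Query, start: int, end: int) -> list[SearchHit]:
        out = []
        for h in self.hits:
            s = max(h.query_span[0], start)
            e = min(h.query_span[1], end)
            if s <= e:
                out.append(replace(h, query_span=(s, e)))
        return out


def make_hit_script(
    domains: list[tuple[tuple[int, int], str, float, float]],
) -> ScriptedBackend:
    """Backend scripted from (span, address, e_value, z_score) tuples;
    target lengths default to the span length."""
    hits = [
        SearchHit(target_id=f"d{k:03d}", target_address=addr,
                  e_value=e, z_score=z, query_span=span,
                  target_len=span[1] - span[0] + 1)
        for k, (span, addr, e, z) in enumerate(domains)
    ]
    return ScriptedBackend(hits)
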