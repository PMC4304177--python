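"""Chain cleaning: sequence reconciliation, MODRES restoration, atom
pruning, alternate-conformation resolution, quality filters, re-indexing.

The central primitive is an asymmetric global alignment that threads the
coordinate-part sequence into the reference (SEQRES) sequence: gaps are
allowed only on the coordinate side, so every coordinate residue is mapped
to a reference position and the unmapped reference positions form the
missing regions.  Scoring is match +1, mismatch 0, gap (skipped reference
position) -0.5, so a substituted or modified residue is anchored as a
mismatch rather than pushed into a gap.  Ties are broken toward the
leftmost placement (lexicographically smallest mapping).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .pdb_io import (
    ChainRecord,
        STANDARD_RESIDUES,
    coord_sequence,
    )

logger = logging.getLogger(__name__)

MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_SCORE = -0.5

# Heavy atoms of the 20 standard amino acids.  Backbone N/CA/C/O is shared;
# OXT is accepted only on the chain's final residue.
_BACKBONE = ("N", "CA", "C", "O")
_SIDECHAINS = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

STANDARD_COMPOSITION: dict[str, frozenset[str]] = {
    res: frozenset(_BACKBONE + side) for res, side in _SIDECHAINS.items()
}


class AlignmentError(ValueError):
    """Raised when the coordinate sequence cannot be threaded into the
    reference sequence."""


@dataclass
class RefCoordAlignment:
    """Mapping of coordinate residues into the reference sequence.

    ``mapping[j]`` is the 1-based reference position of coordinate residue
    ``j+1``; positions are strictly increasing.  ``missing_regions`` are the
    closed intervals of reference positions with no coordinates, exactly the
    complement of the mapped positions.  Mismatched (but mapped) positions
    are listed, not gapped.
    """

    mapping: list[int]
    missing_regions: list[tuple[int, int]]
    mismatches: list[int]
    ref_len: int
    n_matches: int = 0
    flagged_zero_match: bool = False

    @property
    def map_pairs(self) -> list[tuple[int, int]]:
        """(coord_index, ref_position) pairs, both 1-based."""
        return [(j + 1, p) for j, p in enumerate(self.mapping)]


@dataclass
class FilterReport:
    """Verdict of the chain-quality filters."""

    kept: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class CleanParams:
    min_length: int = 30
    max_x_fraction: float = 0.10
    altloc_policy: str = "first"

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 < self.max_x_fraction <= 1:
            raise ValueError("max_x_fraction must be in (0, 1]")
        if self.altloc_policy != "first":
            raise ValueError("only the 'first conformation' policy is supported")


def restore_modres(chain: ChainRecord) -> ChainRecord:
    """Replace modified residue codes by their standard parents via the
    file's MODRES map; restored residues are flagged.  Non-standard codes
    with no mapping stay as they are and contribute 'X' to the
    coordinate-derived sequence."""
    out = copy.deepcopy(chain)
    for res in out.residues:
        if res.res_name in STANDARD_RESIDUES:
            continue
        std = out.modres_map.get(res.res_name)
        if std in STANDARD_RESIDUES:
            res.res_name = std
            res.is_modified = True
    return out


def select_altloc(chain: ChainRecord) -> ChainRecord:
    """Keep only the first conformation (file order) of every atom that has
    alternate locations; the altLoc marker is blanked."""
    out = copy.deepcopy(chain)
    for res in out.residues:
        seen: set[str] = set()
        kept = []
        for atom in res.atoms:
            if atom.name in seen:
                continue
            seen.add(atom.name)
            if atom.alt_loc:
                atom = type(atom)(
                    name=atom.name, element=atom.element, coords=atom.coords,
                    alt_loc="", occupancy=atom.occupancy, serial=atom.serial,
                )
            kept.append(atom)
        res.atoms = kept
    return out


def prune_atoms(chain: ChainRecord) -> ChainRecord:
    """Drop atoms outside the standard heavy-atom composition of each
    residue's (restored) type; OXT survives on the final residue only.
    Residues of unknown type keep nothing beyond the backbone."""
    out = copy.deepcopy(chain)
    n_pruned = 0
    last = len(out.residues) - 1
    for i, res in enumerate(out.residues):
        allowed = STANDARD_COMPOSITION.get(res.res_name, frozenset(_BACKBONE))
        if i == last:
            allowed = allowed | {"OXT"}
        before = len(res.atoms)
        res.atoms = [a for a in res.atoms if a.name in allowed]
        n_pruned += before - len(res.atoms)
    if n_pruned:
        logger.debug("pruned %d non-standard atoms from %s",
                     n_pruned, out.chain_name)
    return out


def count_atoms(chain: ChainRecord) -> int:
    return sum(len(r.atoms) for r in chain.residues)


def align_ref_coord(ref_seq: str, coord_seq: str) -> RefCoordAlignment:
    """Thread ``coord_seq`` into ``ref_seq`` with no gaps allowed in the
    reference, maximizing matches (ties -> leftmost placement).

    Raises AlignmentError when the coordinate sequence is longer than the
    reference.  A zero-match optimum is flagged as an inconsistency.
    """
    if not ref_seq or not coord_seq:
        raise AlignmentError("sequences must be non-empty")
    n, m = len(ref_seq), len(coord_seq)
    if m > n:
        raise AlignmentError(
            f"coordinate sequence ({m}) longer than reference ({n})")

    ref = np.frombuffer(ref_seq.encode("latin1"), dtype=np.uint8)
    coord = np.frombuffer(coord_seq.encode("latin1"), dtype=np.uint8)

    # Suffix DP: S[i, j] = best score threading coord[j:] into ref[i:].
    neg = -np.inf
    S = np.full((n + 1, m + 1), neg)
    S[:, m] = -0.5 * np.arange(n, -1, -1)
    for i in range(n - 1, -1, -1):
        sub = np.where(ref[i] == coord, MATCH_SCORE, MISMATCH_SCORE)
        diag = sub + S[i + 1, 1:]
        skip = GAP_SCORE + S[i + 1, :m]
        S[i, :m] = np.maximum(diag, skip)
    if S[0, 0] == neg:
        raise AlignmentError("no feasible threading")  # pragma: no cover

    # Greedy front-to-back traceback, preferring a (mis)match on ties,
    # yields the lexicographically smallest optimal mapping.
    mapping: list[int] = []
    mismatches: list[int] = []
    n_matches = 0
    i = j = 0
    while j < m:
        sub = MATCH_SCORE if ref_seq[i] == coord_seq[j] else MISMATCH_SCORE
        if sub + S[i + 1, j + 1] >= GAP_SCORE + S[i + 1, j]:
            mapping.append(i + 1)
            if ref_seq[i] == coord_seq[j]:
                n_matches += 1
            else:
                mismatches.append(i + 1)
            j += 1
        i += 1

    mapped = set(mapping)
    missing: list[tuple[int, int]] = []
    start = None
    for p in range(1, n + 1):
        if p not in mapped:
            if start is None:
                start = p
        elif start is not None:
            missing.append((start, p - 1))
            start = None
    if start is not None:
        missing.append((start, n))

    flagged = n_matches == 0
    if flagged:
        logger.warning("zero-match alignment: reference and coordinate "
                       "sequences share no residue")
    return RefCoordAlignment(
        mapping=mapping, missing_regions=missing, mismatches=mismatches,
        ref_len=n, n_matches=n_matches, flagged_zero_match=flagged,
    )


def reindex(chain: ChainRecord, aln: RefCoordAlignment) -> ChainRecord:
    """Renumber coordinate residues by their mapped reference position
    (1-based); insertion codes are cleared."""
    if len(aln.mapping) != len(chain.residues):
        raise ValueError("alignment does not cover this chain's residues")
    out = copy.deepcopy(chain)
    for res, pos in zip(out.residues, aln.mapping):
        res.seq_num = pos
        res.icode = ""
    return out


def apply_filters(chain: ChainRecord, params: CleanParams | None = None
                  ) -> FilterReport:
    """Quality filters: CA-only traces, short sequences, and sequences with
    too many unknown residues are rejected.  Length 30 is kept (the cut is
    strictly below the minimum)."""
    params = params or CleanParams()
    reasons = []
    if chain.residues and all(
            len(r.atoms) >= 1 and {a.name for a in r.atoms} == {"CA"}
            for r in chain.residues):
        reasons.append("CA_ONLY")
    if len(chain.ref_seq) < params.min_length:
        reasons.append("TOO_SHORT")
    if chain.ref_seq:
        frac = chain.ref_seq.count("X") / len(chain.ref_seq)
        if frac > params.max_x_fraction:
            reasons.append("TOO_MANY_X")
    return FilterReport(kept=not reasons, reasons=reasons)


@dataclass
class CleanResult:
    chain: ChainRecord
    alignment: RefCoordAlignment
    report: FilterReport
    n_atoms_pruned: int = 0


def clean_chain(chain: ChainRecord, params: CleanParams | None = None
                ) -> CleanResult:
    """Full cleaning pipeline: restore MODRES codes, resolve alternate
    conformations, prune non-standard atoms, align to the reference,
    re-index, and apply the quality filters.

    The cleaned chain is returned regardless of the filter verdict; the
    verdict is reported separately so callers decide what to drop.
    """
    params = params or CleanParams()
    staged = restore_modres(chain)
    staged = select_altloc(staged)
    before = count_atoms(staged)
    staged = prune_atoms(staged)
    n_pruned = before - count_atoms(staged)
    aln = align_ref_coord(staged.ref_seq, coord_sequence(staged))
    staged = reindex(staged, aln)
    report = apply_filters(staged, params)
    return CleanResult(chain=staged, alignment=aln, report=report,
                       n_atoms_pruned=n_pruned)
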