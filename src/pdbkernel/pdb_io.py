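"""Legacy-PDB parsing and writing at chain granularity.

Chains are the working unit of the toolkit: each chain carries its
reference sequence (from SEQRES), its coordinate residues (from ATOM
records), the file's MODRES map, and experiment metadata (method,
resolution, deposit date) used downstream by the representative-selection
rules.

Only the legacy fixed-column dialect is handled: HEADER, EXPDTA,
REMARK 2 RESOLUTION, SEQRES, MODRES, SOURCE, ATOM/HETATM, MODEL/ENDMDL,
TER, END.  For multi-model (NMR) files only the first model is read.
"""

from __future__ import annotations

import datetime as _dt
import io
import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.PDBData import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 1-letter -> 3-letter codes for the 20 standard amino acids.
AA_1TO3 = {one: three for three, one in protein_letters_3to1.items()}

#: 3-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(protein_letters_3to1)

_MONTHS = {
    "JAN": 1, "FEB": 2, "MAR": 3, "APR": 4, "MAY": 5, "JUN": 6,
    "JUL": 7, "AUG": 8, "SEP": 9, "OCT": 10, "NOV": 11, "DEC": 12,
}
_MONTHS_INV = {v: k for k, v in _MONTHS.items()}

# Two-digit-year pivot: deposits started in 1972, so 71-99 -> 19xx.
_YEAR_PIVOT = 71


class PDBParseError(ValueError):
    """Raised on a malformed fixed-column record; carries the line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class PDBWriteError(ValueError):
    """Raised when a chain cannot be serialized to legacy PDB."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom from an ATOM/HETATM record."""

    name: str
    element: str
    coords: tuple[float, float, float]
    alt_loc: str = ""
    occupancy: float = 1.0
    serial: int = 0

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(x == x and abs(x) != float("inf") for x in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueRecord:
    """One residue of the coordinate part."""

    res_name: str
    seq_num: int
    icode: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    is_modified: bool = False

    @property
    def seq_id(self) -> str:
        return f"{self.seq_num}{self.icode}"


@dataclass
class ChainMeta:
    """Experiment metadata backing the representative-priority rules."""

    pdb_id: str = "XXXX"
    chain_id: str = "A"
    method: str = "OTHER"  # XRAY | NMR | OTHER
    resolution: float | None = None
    deposit_date: _dt.date | None = None
    source: str = ""

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")
        if self.method == "NMR" and self.resolution is not None:
            raise ValueError("NMR structures carry no resolution")


@dataclass
class ChainRecord:
    """One protein chain: reference sequence plus coordinate residues."""

    meta: ChainMeta
    ref_seq: str
    residues: list[ResidueRecord]
    modres_map: dict[str, str] = field(default_factory=dict)
    #: set when no SEQRES existed and ref_seq was derived from coordinates
    ref_from_coords: bool = False

    @property
    def chain_name(self) -> str:
        return f"{self.meta.pdb_id}_{self.meta.chain_id}"


def three_to_one(res_name: str, modres_map: dict[str, str] | None = None) -> str:
    """Translate a 3-letter code to 1-letter; MODRES-mapped codes go through
    their standard parent, anything else becomes 'X'."""
    code = res_name.upper()
    if code in protein_letters_3to1:
        return protein_letters_3to1[code]
    if modres_map:
        std = modres_map.get(code)
        if std in protein_letters_3to1:
            return protein_letters_3to1[std]
    return "X"


def _parse_date(text: str, line_no: int) -> _dt.date | None:
    text = text.strip()
    if not text:
        return None
    try:
        day, mon, yy = text.split("-")
        year = int(yy)
        year += 1900 if year >= _YEAR_PIVOT else 2000
        return _dt.date(year, _MONTHS[mon.upper()], int(day))
    except (ValueError, KeyError) as exc:
        raise PDBParseError(f"bad HEADER date {text!r}: {exc}", line_no) from None


def _float_field(line: str, lo: int, hi: int, what: str, line_no: int) -> float:
    raw = line[lo:hi]
    try:
        return float(raw)
    except ValueError:
        raise PDBParseError(f"bad {what} field {raw!r}", line_no) from None


def _int_field(line: str, lo: int, hi: int, what: str, line_no: int) -> int:
    raw = line[lo:hi]
    try:
        return int(raw)
    except ValueError:
        raise PDBParseError(f"bad {what} field {raw!r}", line_no) from None


def parse_pdb(text: str) -> list[ChainRecord]:
    """Parse a legacy PDB file into one ChainRecord per chain with ATOM records.

    SEQRES is translated to 1-letter codes (unknowns -> 'X', MODRES-covered
    codes through their standard parent).  HETATM residues are kept only when
    their code is covered by MODRES and listed in the chain's SEQRES; all
    other HETATM content (waters, ligands) is dropped.  Chains with ATOM
    records but no SEQRES get a coordinate-derived reference sequence and are
    flagged.  Chains present only in SEQRES are skipped and logged.
    """
    pdb_id = "XXXX"
    method = "OTHER"
    resolution: float | None = None
    deposit_date: _dt.date | None = None
    source_parts: list[str] = []
    seqres: dict[str, list[str]] = {}
    modres: dict[str, str] = {}
    # chain -> {(seq_num, icode): ResidueRecord}, insertion-ordered
    chains: dict[str, dict[tuple[int, str], ResidueRecord]] = {}
    hetatm_names: dict[str, set[str]] = {}
    het_residues: set[tuple[str, int, str]] = set()
    in_model = 0
    saw_atom = False

    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "HEADER":
            pdb_id = line[62:66].strip() or pdb_id
            deposit_date = _parse_date(line[50:59], line_no)
        elif rec == "EXPDTA":
            tag = line[10:].upper()
            if "X-RAY" in tag or "XRAY" in tag:
                method = "XRAY"
            elif "NMR" in tag:
                method = "NMR"
            else:
                method = "OTHER"
        elif rec == "REMARK" and line[7:10].strip() == "2":
            body = line[11:].upper()
            if "RESOLUTION" in body and "NOT APPLICABLE" not in body:
                for tok in body.replace("RESOLUTION.", " ").split():
                    try:
                        resolution = float(tok)
                        break
                    except ValueError:
                        continue
        elif rec == "SOURCE":
            source_parts.append(line[10:].strip())
        elif rec == "SEQRES":
            if len(line) < 19:
                raise PDBParseError("truncated SEQRES record", line_no)
            chain_id = line[11]
            seqres.setdefault(chain_id, []).extend(line[19:].split())
        elif rec == "MODRES":
            if len(line) < 27:
                raise PDBParseError("truncated MODRES record", line_no)
            mod = line[12:15].strip()
            std = line[24:27].strip()
            if mod and std:
                modres[mod] = std
        elif rec == "MODEL ":
            in_model += 1
        elif rec == "ENDMDL":
            pass
        elif rec in ("ATOM  ", "HETATM"):
            if in_model > 1:
                continue  # only the first model of NMR ensembles
            if len(line) < 54:
                raise PDBParseError(f"truncated {rec.strip()} record", line_no)
            serial = _int_field(line, 6, 11, "serial", line_no)
            name = line[12:16].strip()
            if not name:
                raise PDBParseError("empty atom name", line_no)
            alt_loc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21]
            seq_num = _int_field(line, 22, 26, "residue number", line_no)
            icode = line[26].strip()
            x = _float_field(line, 30, 38, "x", line_no)
            y = _float_field(line, 38, 46, "y", line_no)
            z = _float_field(line, 46, 54, "z", line_no)
            occ_raw = line[54:60].strip()
            occupancy = float(occ_raw) if occ_raw else 1.0
            element = line[76:78].strip() if len(line) >= 78 else ""
            is_het = rec == "HETATM"
            if is_het:
                hetatm_names.setdefault(chain_id, set()).add(res_name)
                if res_name not in modres:
                    continue  # water / ligand chemistry is out of scope
            saw_atom = True
            atom = AtomRecord(
                name=name, element=element, coords=(x, y, z),
                alt_loc=alt_loc, occupancy=occupancy, serial=serial,
            )
            residues = chains.setdefault(chain_id, {})
            key = (seq_num, icode)
            if key not in residues:
                residues[key] = ResidueRecord(res_name, seq_num, icode)
                if is_het:
                    het_residues.add((chain_id,) + key)
            residues[key].atoms.append(atom)

    if not saw_atom:
        raise PDBParseError("no ATOM records in file", 0)

    if method == "NMR":
        resolution = None

    records: list[ChainRecord] = []
    for chain_id, residues in chains.items():
        res_list = list(residues.values())
        # HETATM residues are retained only when listed in SEQRES as well
        # (MODRES coverage was already required at parse time).
        sr = seqres.get(chain_id)
        if sr is not None:
            sr_set = set(sr)
            res_list = [
                r for r in res_list
                if (chain_id, r.seq_num, r.icode) not in het_residues
                or r.res_name in sr_set
            ]
        if not res_list:
            continue
        if sr is None:
            ref = "".join(three_to_one(r.res_name, modres) for r in res_list)
            flagged = True
            logger.warning("chain %s has ATOM records but no SEQRES; "
                           "reference sequence derived from coordinates",
                           chain_id)
        else:
            ref = "".join(three_to_one(code, modres) for code in sr)
            flagged = False
        meta = ChainMeta(
            pdb_id=pdb_id, chain_id=chain_id, method=method,
            resolution=resolution, deposit_date=deposit_date,
            source=" ".join(p for p in source_parts if p),
        )
        records.append(ChainRecord(
            meta=meta, ref_seq=ref, residues=res_list,
            modres_map=dict(modres), ref_from_coords=flagged,
        ))

    for chain_id in seqres:
        if chain_id not in chains:
            logger.info("chain %s listed in SEQRES but has no ATOM records; "
                        "skipped", chain_id)
    return records


def _format_date(date: _dt.date | None) -> str:
    if date is None:
        return ""
    return f"{date.day:02d}-{_MONTHS_INV[date.month]}-{date.year % 100:02d}"


_EXPDTA_TEXT = {"XRAY": "X-RAY DIFFRACTION", "NMR": "SOLUTION NMR",
                "OTHER": "OTHER"}


def write_clean_pdb(chain: ChainRecord) -> str:
    """Serialize a cleaned chain to legacy PDB text.

    The output carries SEQRES for the reference sequence and ATOM records
    using the re-indexed residue numbering, so that re-parsing reproduces
    the record's sequences, coordinates (to the format's 3 decimals) and
    metadata.
    """
    m = chain.meta
    lines = [
        f"HEADER    {'PROTEIN':<40}{_format_date(m.deposit_date):>9}   "
        f"{m.pdb_id:<4}".rstrip(),
        f"EXPDTA    {_EXPDTA_TEXT.get(m.method, 'OTHER')}",
    ]
    if m.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {m.resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    if m.source:
        lines.append(f"SOURCE    {m.source}")

    three = [AA_1TO3.get(c, "UNK") for c in chain.ref_seq]
    n = len(three)
    for i, start in enumerate(range(0, n, 13), start=1):
        block = " ".join(f"{t:>3}" for t in three[start:start + 13])
        lines.append(f"SEQRES {i:>3} {m.chain_id} {n:>4}  {block}")

    serial = 0
    for res in chain.residues:
        seen: set[str] = set()
        for atom in res.atoms:
            if atom.name in seen:
                raise PDBWriteError(
                    f"duplicate atom {atom.name!r} in residue "
                    f"{res.res_name} {res.seq_id}")
            seen.add(atom.name)
            serial += 1
            nm = atom.name
            # column 13 is reserved for two-letter element symbols
            pad = f" {nm:<3}" if len(nm) < 4 and not nm[:1].isdigit() else f"{nm:<4}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:>5} {pad}{atom.alt_loc or ' '}"
                f"{res.res_name:>3} {m.chain_id}{res.seq_num:>4}"
                f"{res.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2}"
            )
    last = chain.residues[-1] if chain.residues else None
    if last is not None:
        serial += 1
        lines.append(f"TER   {serial:>5}      {last.res_name:>3} "
                     f"{m.chain_id}{last.seq_num:>4}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_sequences(chains: list[ChainRecord]) -> str:
    """FASTA export of reference sequences, one entry per chain,
    headers ``pdbid_chain``."""
    records = [
        SeqRecord(Seq(c.ref_seq), id=c.chain_name, description="")
        for c in chains
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def coord_sequence(chain: ChainRecord) -> str:
    """1-letter sequence of the coordinate part (standard codes only;
    anything non-standard contributes 'X')."""
    return "".join(
        protein_letters_3to1.get(r.res_name, "X") for r in chain.residues
    )
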