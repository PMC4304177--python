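import datetime as dt

import numpy as np
import pytest

from pdbkernel import fixtures as fx
from pdbkernel.pdb_io import (
    AtomRecord,
    ChainMeta,
    ChainRecord,
    ResidueRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def build_chain(seq: str, coord_positions=None, atoms=("N", "CA", "C", "O"),
                res_names=None, **meta_kwargs) -> ChainRecord:
    """Hand-assembled ChainRecord with idealized coordinates."""
    coord_positions = coord_positions or list(range(1, len(seq) + 1))
    meta = ChainMeta(**{"pdb_id": "TST1", "chain_id": "A", "method": "XRAY",
                        "resolution": 2.0,
                        "deposit_date": dt.date(2010, 1, 1),
                        **meta_kwargs})
    residues = []
    for pos in coord_positions:
        name3 = (res_names or {}).get(pos) or fx.AA_1TO3.get(seq[pos - 1], "UNK")
        res = ResidueRecord(name3, pos)
        for i, a in enumerate(atoms):
            res.atoms.append(AtomRecord(
                name=a, element=a[0],
                coords=(round(3.8 * pos + 0.3 * i, 3), float(i), 0.0)))
        residues.append(res)
    return ChainRecord(meta=meta, ref_seq=seq, residues=residues)


@pytest.fixture(scope="session")
def fixture_suite():
    """A reusable batch of randomized defect fixtures with ground truth."""
    rng = np.random.default_rng(991)
    return [fx.random_defect_fixture(rng) for _ in range(60)]
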