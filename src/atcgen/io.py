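"""Tabular I/O for compound datasets and descriptor matrices.

Dataset files are UTF-8 CSV/TSV with a header and columns ``compound_id``,
``smiles``, ``atc_codes`` (semicolon-separated 5-character codes) plus
optional ``mol_weight`` and ``source``.  Descriptor files are CSV with
``compound_id`` first and named descriptor columns after it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atc import AtcCode, CompoundRecord
from .chem import DescriptorMatrix

_REQUIRED = ("compound_id", "smiles", "atc_codes")


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(path: str | Path) -> list[CompoundRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        codes = frozenset(
            AtcCode(c.strip()) for c in row.atc_codes.split(";") if c.strip()
        )
        mw = getattr(row, "mol_weight", "")
        records.append(
            CompoundRecord(
                compound_id=row.compound_id,
                smiles=row.smiles,
                atc_codes=codes,
                source=getattr(row, "source", ""),
                mol_weight=float(mw) if mw not in ("", None) else None,
            )
        )
    return records


def write_dataset(records: list[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "atc_codes": [";".join(sorted(r.code_strings())) for r in records],
            "mol_weight": [
                "" if r.mol_weight is None else r.mol_weight for r in records
            ],
            "source": [r.source for r in records],
        }
    )
    df.to_csv(path, sep=_sep(path), index=False)


def read_descriptors(path: str | Path) -> tuple[list[str], DescriptorMatrix]:
    """Load a precomputed descriptor CSV; returns (compound_ids, matrix)."""
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    names = list(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, DescriptorMatrix(names=names, values=values)


def write_descriptors(
    ids: list[str], matrix: DescriptorMatrix, path: str | Path
) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.names)
    df.insert(0, "compound_id", ids)
    df.to_csv(path, index=False)
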