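"""Compound standardization, filtering, merging and descriptor featurization.

The preprocessing pipeline mirrors common practice when unifying drug
databases for structure-based modelling:

1. every SMILES is standardized (monatomic counterions removed, charges
   neutralized where chemically valid, canonicalized) so that canonical
   string equality deduplicates compounds across sources;
2. records are filtered — compounds whose ATC annotation is entirely in the
   first-level "V" (various) group are excluded except the V03AX chemical
   subgroup, multicomponent structures are dropped, and an optional
   molecular-weight cutoff restricts the set to small molecules;
3. 1D/2D molecular descriptors are computed per compound, pruned of
   constant/all-missing and highly correlated columns, median-imputed and
   z-scored with statistics fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atc import AtcCode, CompoundRecord, level_prefix


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def _rdkit():
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem.MolStandardize import rdMolStandardize
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "RDKit is required for SMILES standardization and descriptor "
            "computation; install rdkit or supply a precomputed descriptor file"
        ) from exc
    RDLogger.DisableLog("rdApp.*")
    return Chem, rdMolStandardize


def standardize_smiles(raw: str) -> str:
    """Standardize and canonicalize a SMILES string.

    Monatomic charged fragments (Na+, Cl-, ...) are removed as counterions,
    remaining fragments are charge-neutralized where chemically valid, and
    the result is emitted as RDKit canonical SMILES.  The operation is
    idempotent: re-standardizing the output returns it unchanged.

    Raises
    ------
    SmilesParseError
        If ``raw`` is empty or not parseable.
    """
    if not raw or not raw.strip():
        raise SmilesParseError("empty SMILES string")
    Chem, rdMolStandardize = _rdkit()
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {raw!r}")
    mol = rdMolStandardize.Cleanup(mol)
    frags = Chem.GetMolFrags(mol, asMols=True)
    kept = [
        f
        for f in frags
        if not (f.GetNumAtoms() == 1 and f.GetAtomWithIdx(0).GetFormalCharge() != 0)
    ]
    if not kept:  # nothing but counterions: keep the molecule as cleaned
        kept = list(frags)
    combined = kept[0]
    for f in kept[1:]:
        combined = Chem.CombineMols(combined, f)
    combined = rdMolStandardize.Uncharger().uncharge(combined)
    return Chem.MolToSmiles(combined)


def _keep_code(code: AtcCode) -> bool:
    # first-level "V" excluded unless the level-4 prefix is exactly V03AX
    if code.prefix(1) != "V":
        return True
    return code.prefix(4) == "V03AX"


def filter_dataset(
    records: list[CompoundRecord], mw_cutoff: float = 900.0
) -> list[CompoundRecord]:
    """Apply the dataset inclusion rules; filtering is total (never raises).

    Drops records lacking SMILES or ATC codes; removes ATC codes in the
    first-level "V" group (except the V03AX subgroup) and drops records whose
    code set becomes empty; drops multicomponent structures (standardized
    SMILES still containing ``.``); drops records heavier than ``mw_cutoff``
    Daltons when a molecular weight is recorded.
    """
    out: list[CompoundRecord] = []
    for rec in records:
        if not rec.smiles or not rec.atc_codes:
            continue
        if "." in rec.smiles:
            continue
        if rec.mol_weight is not None and rec.mol_weight > mw_cutoff:
            continue
        codes = frozenset(c for c in rec.atc_codes if _keep_code(c))
        if not codes:
            continue
        out.append(rec.with_codes(codes) if codes != rec.atc_codes else rec)
    return out


def merge_sources(
    source_lists: list[list[CompoundRecord]],
) -> list[CompoundRecord]:
    """Merge per-source record lists on canonical SMILES.

    Records sharing a canonical SMILES collapse into one record whose code
    set is the union; the first-seen compound_id is kept and sources are
    joined with ``+``.  Output order follows first appearance.
    """
    merged: dict[str, CompoundRecord] = {}
    for records in source_lists:
        for rec in records:
            prev = merged.get(rec.smiles)
            if prev is None:
                merged[rec.smiles] = rec
            else:
                sources = prev.source
                if rec.source and rec.source not in sources.split("+"):
                    sources = f"{sources}+{rec.source}" if sources else rec.source
                merged[rec.smiles] = CompoundRecord(
                    compound_id=prev.compound_id,
                    smiles=prev.smiles,
                    atc_codes=prev.atc_codes | rec.atc_codes,
                    source=sources,
                    mol_weight=prev.mol_weight
                    if prev.mol_weight is not None
                    else rec.mol_weight,
                )
    return list(merged.values())


@dataclass
class DescriptorMatrix:
    """Per-compound numeric descriptor vectors.

    ``values`` is a compounds × descriptors float array with NaN marking
    non-computable cells.  ``kept_mask`` records pruning decisions;
    ``means``/``stds``/``medians`` hold standardization statistics fitted on
    training rows (aligned with kept columns).
    """

    names: list[str]
    values: np.ndarray
    kept_mask: np.ndarray | None = None
    means: np.ndarray | None = None
    stds: np.ndarray | None = None
    medians: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values shape does not match descriptor names")
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.names), dtype=bool)

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    def kept_names(self) -> list[str]:
        return [n for n, k in zip(self.names, self.kept_mask) if k]

    def kept_values(self) -> np.ndarray:
        return self.values[:, self.kept_mask]


def compute_descriptors(smiles_list: list[str]) -> DescriptorMatrix:
    """Compute 1D/2D molecular descriptors for each SMILES.

    One row per compound; cells the descriptor engine cannot evaluate are
    NaN.  An empty input yields a 0-row matrix with the full name list.
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "descriptor engine (RDKit) unavailable: supply a precomputed "
            "descriptor CSV via load_descriptor_csv instead"
        ) from exc
    RDLogger.DisableLog("rdApp.*")
    names = [name for name, _ in Descriptors.descList]
    rows = np.full((len(smiles_list), len(names)), np.nan)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise SmilesParseError(f"unparsable SMILES: {smi!r}")
        vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
        rows[i] = [float(vals[n]) for n in names]
    rows[~np.isfinite(rows)] = np.nan
    return DescriptorMatrix(names=names, values=rows)


def prune_descriptors(
    matrix: DescriptorMatrix, corr_threshold: float = 0.95
) -> DescriptorMatrix:
    """Drop constant/all-missing columns, then greedily decorrelate.

    Columns are visited in order; a column is dropped when its absolute
    Pearson correlation with an already-kept column exceeds
    ``corr_threshold``.  Keep-first greedy order makes pruning deterministic.
    """
    if not 0 < corr_threshold <= 1:
        raise ValueError(f"corr_threshold must be in (0, 1], got {corr_threshold}")
    if matrix.n_compounds < 2:
        raise ValueError("pruning requires at least 2 compounds")
    X = matrix.values
    kept = np.zeros(X.shape[1], dtype=bool)
    with np.errstate(all="ignore"):
        col_std = np.nanstd(X, axis=0)
        all_missing = np.all(np.isnan(X), axis=0)
    candidates = np.where(~all_missing & (col_std > 0))[0]

    # NaNs are filled with the column median for the correlation screen only
    filled = X[:, candidates].copy()
    med = np.nanmedian(filled, axis=0)
    nan_r, nan_c = np.where(np.isnan(filled))
    filled[nan_r, nan_c] = med[nan_c]
    std = filled.std(axis=0)
    ok = std > 0  # median fill can flatten a near-all-missing column
    candidates, filled, std = candidates[ok], filled[:, ok], std[ok]
    Z = (filled - filled.mean(axis=0)) / std
    corr = np.abs(Z.T @ Z) / Z.shape[0]

    kept_local: list[int] = []
    for j in range(len(candidates)):
        if all(corr[j, i] <= corr_threshold for i in kept_local):
            kept_local.append(j)
    kept[candidates[kept_local]] = True
    return replace(matrix, kept_mask=kept, means=None, stds=None, medians=None)


def fit_apply_standardization(
    matrix: DescriptorMatrix, fit_rows: np.ndarray | list[int]
) -> DescriptorMatrix:
    """Impute and z-score kept columns using statistics from ``fit_rows``.

    Missing cells are imputed with the fit-rows median of their column; each
    kept column is centered and scaled by the fit-rows mean and std (a zero
    std scales by 1).  The fitted statistics are stored for reuse on new
    data via :func:`apply_standardization`.
    """
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    keep = matrix.kept_mask
    X = matrix.values[:, keep]
    fit = X[fit_rows]
    with np.errstate(all="ignore"):
        medians = np.nanmedian(fit, axis=0)
        medians = np.where(np.isnan(medians), 0.0, medians)
    Xi = np.where(np.isnan(X), medians, X)
    means = Xi[fit_rows].mean(axis=0)
    stds = Xi[fit_rows].std(axis=0)
    stds = np.where(stds == 0, 1.0, stds)
    out_values = matrix.values.copy()
    out_values[:, keep] = (Xi - means) / stds
    return replace(
        matrix, values=out_values, means=means, stds=stds, medians=medians
    )


def apply_standardization(
    matrix: DescriptorMatrix, fitted: DescriptorMatrix
) -> DescriptorMatrix:
    """Apply previously fitted imputation/scaling statistics to new rows."""
    if fitted.means is None:
        raise ValueError("fitted matrix carries no standardization statistics")
    keep = fitted.kept_mask
    X = matrix.values[:, keep]
    Xi = np.where(np.isnan(X), fitted.medians, X)
    out_values = matrix.values.copy()
    out_values[:, keep] = (Xi - fitted.means) / fitted.stds
    return replace(
        matrix,
        values=out_values,
        kept_mask=keep.copy(),
        means=fitted.means,
        stds=fitted.stds,
        medians=fitted.medians,
    )
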