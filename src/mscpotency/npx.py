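"""NPX data model, quality filters, condition profiling and differential secretion.

NPX (Normalized Protein eXpression) is a relative protein quantification unit on a
log2 scale produced by proximity-extension-assay (PEA) panels.  This module holds the
tabular data model for a protein x sample NPX matrix with a sample -> condition
design, the two standard quality filters (below-LOD removal and per-protein
missingness exclusion), per-condition mean profiling, and per-protein one-way ANOVA
with Benjamini-Hochberg adjustment across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Canonical supernatant condition labels, in presentation order.
CONDITIONS = ("Medium", "PBMC", "rMSC", "Coculture", "D3cMSC")

#: Short condition keys used by :class:`ConditionProfile` and the classifier.
CONDITION_KEYS = {"Medium": "med", "PBMC": "pbmc", "rMSC": "rmsc",
                  "Coculture": "coc", "D3cMSC": "d3"}

_ABS_TOL = 1e-9  # absolute tolerance on threshold comparisons


class NPXError(ValueError):
    """Raised on malformed NPX inputs (duplicates, unknown conditions, ...)."""


@dataclass
class NPXMatrix:
    """Protein x sample matrix of log2-scale NPX values with a condition design.

    Missing cells are encoded as NaN in ``values``; ``missing_mask`` is the derived
    boolean view.  ``design`` maps every sample id to one of :data:`CONDITIONS`.
    """

    values: pd.DataFrame              # proteins x samples, NaN = missing
    design: pd.Series                 # sample -> condition
    removed_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        dup_p = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_p:
            raise NPXError(f"duplicate protein ids: {dup_p}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_s:
            raise NPXError(f"duplicate sample ids: {dup_s}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise NPXError(f"samples without condition in design: {missing}")
        bad = sorted(set(self.design.loc[list(self.values.columns)]) - set(CONDITIONS))
        if bad:
            raise NPXError(
                f"unknown condition labels {bad}; expected one of {list(CONDITIONS)}")
        self.design = self.design.loc[list(self.values.columns)]

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.design.index[self.design == condition])


@dataclass
class ConditionProfile:
    """One protein's mean NPX per condition; the classifier's unit of work."""

    protein: str
    med: float
    pbmc: float
    rmsc: float
    coc: float
    d3: float
    n_per_condition: dict[str, int] = field(default_factory=dict)
    sections: str = ""  # printed-table section annotation, where applicable

    def as_dict(self) -> dict[str, float]:
        return {"med": self.med, "pbmc": self.pbmc, "rmsc": self.rmsc,
                "coc": self.coc, "d3": self.d3}

    @property
    def classifiable(self) -> bool:
        return all(np.isfinite(v) for v in self.as_dict().values())


@dataclass
class DiffResult:
    """Per-protein one-way ANOVA result with BH-adjusted p value."""

    protein: str
    f_stat: float
    p_value: float
    p_adjusted: float
    significant: bool
    tested: bool = True


def _to_float(x) -> float:
    """Parse a numeric cell, accepting decimal commas as printed in PEA tables."""
    if isinstance(x, str):
        x = x.strip().replace(",", ".")
        if x == "":
            return np.nan
    return float(x)


def _read_design(design_path) -> pd.Series:
    design_df = pd.read_csv(design_path)
    required = {"sample", "condition"}
    if not required.issubset(design_df.columns):
        raise NPXError(f"design file must have columns {sorted(required)}")
    dup = design_df["sample"][design_df["sample"].duplicated()].tolist()
    if dup:
        raise NPXError(f"duplicate samples in design: {dup}")
    return pd.Series(design_df["condition"].values,
                     index=design_df["sample"].astype(str).values)


def read_npx_table(path, layout: str = "wide", design_path=None,
                   design: pd.Series | None = None) -> tuple[NPXMatrix, "LODTable"]:
    """Read an NPX table (wide or long CSV) plus its design into an :class:`NPXMatrix`.

    Wide layout: first column ``protein``, remaining columns are sample ids.
    Long layout: columns ``sample, protein, npx`` and optionally ``lod``.
    Decimal commas are normalised to dots.  Returns ``(matrix, lod_table)``; the LOD
    table is empty for wide inputs (no LOD column in that dialect).
    """
    if design is None:
        if design_path is None:
            raise NPXError("a design (path or Series) is required")
        design = _read_design(design_path)

    lod: dict[str, float] = {}
    if layout == "wide":
        df = pd.read_csv(path, dtype=str)
        if df.columns[0] != "protein":
            raise NPXError("wide layout requires first column 'protein'")
        df = df.set_index("protein")
        values = df.map(_to_float) if hasattr(df, "map") else df.applymap(_to_float)
    elif layout == "long":
        df = pd.read_csv(path, dtype=str)
        needed = {"sample", "protein", "npx"}
        if not needed.issubset(df.columns):
            raise NPXError(f"long layout requires columns {sorted(needed)}")
        df["npx"] = df["npx"].map(_to_float)
        dup = df.duplicated(subset=["sample", "protein"])
        if dup.any():
            pairs = df.loc[dup, ["sample", "protein"]].values.tolist()
            raise NPXError(f"duplicate (sample, protein) entries: {pairs}")
        values = df.pivot(index="protein", columns="sample", values="npx")
        if "lod" in df.columns:
            lod_series = df.dropna(subset=["lod"]).groupby("protein")["lod"].first()
            lod = {p: _to_float(v) for p, v in lod_series.items()}
    else:
        raise NPXError(f"unknown layout {layout!r}; expected 'wide' or 'long'")

    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return NPXMatrix(values=values, design=design), LODTable(lod)


@dataclass
class LODTable:
    """Protein -> limit of detection (log2 NPX units).

    A protein absent from the table is simply not LOD-filtered.
    """

    limits: dict[str, float] = field(default_factory=dict)

    def __contains__(self, protein: str) -> bool:
        return protein in self.limits

    def __getitem__(self, protein: str) -> float:
        return self.limits[protein]


def apply_lod_filter(matrix: NPXMatrix, lod: LODTable) -> NPXMatrix:
    """Mark every cell strictly below its protein's LOD as missing.

    The boundary value (cell == LOD) is retained; no rows or columns are dropped.
    """
    values = matrix.values.copy()
    for protein, limit in lod.limits.items():
        if protein in values.index:
            row = values.loc[protein]
            values.loc[protein] = row.where(~(row < limit - _ABS_TOL))
    return NPXMatrix(values=values, design=matrix.design,
                     removed_proteins=list(matrix.removed_proteins))


def filter_missingness(matrix: NPXMatrix,
                       max_missing_frac: float = 0.5) -> NPXMatrix:
    """Drop proteins whose missing fraction over all samples is strictly > the cap."""
    frac = matrix.missing_mask.mean(axis=1)
    removed = list(frac.index[frac > max_missing_frac + _ABS_TOL])
    kept = matrix.values.drop(index=removed)
    if kept.empty:
        warnings.warn("all proteins removed by missingness filter", stacklevel=2)
    return NPXMatrix(values=kept, design=matrix.design,
                     removed_proteins=list(matrix.removed_proteins) + removed)


def condition_means(matrix: NPXMatrix) -> list[ConditionProfile]:
    """Per-protein mean NPX per condition over non-missing cells.

    Profiles missing any of the five conditions are returned with NaN in that slot
    and are flagged unclassifiable via :attr:`ConditionProfile.classifiable`.
    """
    groups = {c: matrix.condition_samples(c) for c in CONDITIONS}
    profiles = []
    for protein, row in matrix.values.iterrows():
        means, counts = {}, {}
        for cond, samples in groups.items():
            vals = row.loc[samples].dropna()
            key = CONDITION_KEYS[cond]
            means[key] = float(vals.mean()) if len(vals) else np.nan
            counts[cond] = int(len(vals))
        profiles.append(ConditionProfile(protein=protein, n_per_condition=counts,
                                         **means))
    return profiles


def differential_secretion(matrix: NPXMatrix, alpha: float = 0.01,
                           welch: bool = False) -> list[DiffResult]:
    """One-way ANOVA per protein across condition groups, BH-adjusted.

    A protein is testable when at least two conditions have >= 2 non-missing
    samples; untestable proteins are reported with ``tested=False`` and excluded
    from the BH family.  A protein with zero variance everywhere and equal group
    means gets p = 1 by convention.
    """
    groups = {c: matrix.condition_samples(c) for c in CONDITIONS}
    raw: list[tuple[str, float, float]] = []
    untestable: list[str] = []
    for protein, row in matrix.values.iterrows():
        data = [row.loc[s].dropna().to_numpy() for s in groups.values()]
        data = [g for g in data if len(g) >= 2]
        if len(data) < 2:
            untestable.append(protein)
            continue
        pooled = np.concatenate(data)
        if np.ptp(pooled) < _ABS_TOL:  # all values identical -> no effect
            raw.append((protein, 0.0, 1.0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if welch:
                f, p = _welch_anova(data)
            else:
                res = stats.f_oneway(*data)
                f, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(p):
            f, p = 0.0, 1.0
        raw.append((protein, f, p))

    results: list[DiffResult] = []
    if raw:
        pvals = np.array([p for _, _, p in raw])
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        for (protein, f, p), q in zip(raw, padj):
            results.append(DiffResult(protein=protein, f_stat=f, p_value=p,
                                      p_adjusted=float(q),
                                      significant=bool(q < alpha - _ABS_TOL)))
    for protein in untestable:
        results.append(DiffResult(protein=protein, f_stat=np.nan, p_value=np.nan,
                                  p_adjusted=np.nan, significant=False,
                                  tested=False))
    return results


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (variance-weighted group means)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    v = np.where(v < _ABS_TOL, _ABS_TOL, v)
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    b = 1 + 2 * (k - 2) / (k**2 - 1) * np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    f = a / b
    df2 = (k**2 - 1) / (3 * np.sum((1 - w / np.sum(w)) ** 2 / (n - 1)))
    p = float(stats.f.sf(f, k - 1, df2))
    return float(f), p


def diff_results_frame(results: list[DiffResult]) -> pd.DataFrame:
    """Tabulate :class:`DiffResult` records as a DataFrame."""
    return pd.DataFrame(
        {"protein": [r.protein for r in results],
         "F": [r.f_stat for r in results],
         "p": [r.p_value for r in results],
         "padj": [r.p_adjusted for r in results],
         "significant": [r.significant for r in results],
         "tested": [r.tested for r in results]})
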