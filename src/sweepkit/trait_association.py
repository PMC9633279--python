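"""Genotype-frequency tables and linear-model genotype-trait association.

The association model is the additive-dosage linear model
``y = b0 + b·x + sex + batch + e`` with x the number of copies (0/1/2) of the
tested (deletion) allele, fitted by ordinary least squares with two-sided
t tests on the coefficients.  A two-locus variant adds the product term
``g1·g2`` to test an epistatic interaction.  Analysis is complete-case:
samples with a missing genotype, trait or covariate are dropped; covariates
that are constant in the analysed subset (e.g. sex in an all-female yield
panel) are dropped with a note rather than breaking the fit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "FrequencyTable",
    "AssociationResult",
    "genotype_frequency_table",
    "ols_fit",
    "associate_variant",
    "interaction_association",
]

logger = logging.getLogger(__name__)

PERFECT_FIT = "PERFECT_FIT"


@dataclass
class FrequencyTable:
    """Per-group genotype counts and derived frequencies for one variant."""

    variant_id: str
    table: pd.DataFrame  # index: group; columns n_called, n0, n1, n2, alt_freq, hom_alt_freq, het_freq

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class AssociationResult:
    """OLS fit summary: per-term estimates, SEs, t statistics, p-values."""

    table: pd.DataFrame  # index: term; columns estimate, se, t, p
    df_resid: int
    n: int
    formula: str
    focus: str | None = None
    flags: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def focus_row(self) -> pd.Series:
        if self.focus is None:
            raise ValueError("no focus term set")
        return self.table.loc[self.focus]

    def to_json_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n": self.n,
            "df_resid": self.df_resid,
            "terms": self.table.reset_index().to_dict(orient="records"),
            "focus": self.focus,
            "flags": self.flags,
            "notes": self.notes,
        }


def genotype_frequency_table(
    gm: GenotypeMatrix, variant_id: str, grouping: str = "population"
) -> FrequencyTable:
    """Dosage genotype counts and frequencies per group for one variant.

    Reports, per group: called-sample count, counts of dosage 0/1/2, alternate
    (deletion) allele frequency, homozygous-alt frequency and heterozygote
    frequency — all over non-missing calls.
    """
    vi = gm.find_variant(variant_id)
    if gm.sample_meta is None or grouping not in gm.sample_meta.columns:
        raise ValueError(f"grouping column {grouping!r} not in sample metadata")
    groups = gm.sample_meta.loc[gm.samples, grouping].astype(str).to_numpy()
    dos = gm.dosage[:, vi]
    rows = {}
    for grp in pd.unique(groups):
        d = dos[groups == grp]
        d = d[d != MISSING]
        n = d.size
        n0, n1, n2 = int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
        if n == 0:
            rows[grp] = dict(n_called=0, n0=0, n1=0, n2=0,
                             alt_freq=np.nan, hom_alt_freq=np.nan, het_freq=np.nan)
        else:
            rows[grp] = dict(
                n_called=n, n0=n0, n1=n1, n2=n2,
                alt_freq=(n1 + 2 * n2) / (2.0 * n),
                hom_alt_freq=n2 / n,
                het_freq=n1 / n,
            )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = grouping
    return FrequencyTable(variant_id=variant_id, table=table)


def _encode_design(X: pd.DataFrame, add_intercept: bool = True) -> pd.DataFrame:
    """Numeric columns pass through; categoricals one-hot encoded dropping the first level."""
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["Intercept"] = np.ones(len(X))
    for name in X.columns:
        col = X[name]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
            cols[name] = col.to_numpy(dtype=float)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=X.index)


def _collinear_columns(M: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(M)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[k] for k in np.flatnonzero(diag < tol)]


def ols_fit(y, X: pd.DataFrame, add_intercept: bool = True, focus: str | None = None) -> AssociationResult:
    """Ordinary least squares with t tests.

    ``X`` is a DataFrame of predictors; categorical/object columns are
    one-hot encoded dropping the first (reference) level, and an intercept is
    prepended unless disabled.  SEs come from s²(XᵀX)⁻¹ with
    s² = SSE / (n − rank); a numerically perfect fit reports p = 0 with a
    PERFECT_FIT flag.  Rank deficiency is an error naming the collinear
    columns.
    """
    y = np.asarray(y, dtype=float)
    D = _encode_design(X, add_intercept=add_intercept)
    names = list(D.columns)
    M = D.to_numpy(dtype=float)
    n, p = M.shape
    if n <= p:
        raise ValueError(f"n={n} samples cannot identify {p} coefficients")
    rank = int(np.linalg.matrix_rank(M))
    if rank < p:
        raise ValueError(f"design is rank deficient; collinear columns: {_collinear_columns(M, names)}")
    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    sse = float(resid @ resid)
    df = n - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    tss = float(np.sum((y - y.mean()) ** 2))
    flags: list[str] = []
    xtx_inv = np.linalg.inv(M.T @ M)
    if sse <= max(tss, 1.0) * 1e-12:
        se = np.zeros(p)
        t = np.where(beta == 0, 0.0, np.inf * np.sign(beta))
        pvals = np.where(beta == 0, 1.0, 0.0)
        flags.append(PERFECT_FIT)
    else:
        s2 = sse / df
        se = np.sqrt(s2 * np.diag(xtx_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        pvals = 2.0 * sps.t.sf(np.abs(t), df)
    table = pd.DataFrame({"estimate": beta, "se": se, "t": t, "p": pvals}, index=names)
    table.index.name = "term"
    formula = "y ~ " + " + ".join(names)
    return AssociationResult(table=table, df_resid=df, n=n, formula=formula, focus=focus, flags=flags)


def _complete_case_frame(
    gm: GenotypeMatrix,
    dosage_cols: dict[str, int],
    trait: str,
    covariates: tuple[str, ...],
) -> pd.DataFrame:
    if gm.sample_meta is None:
        raise ValueError("no sample metadata attached")
    meta = gm.sample_meta.loc[gm.samples]
    if trait not in meta.columns:
        raise ValueError(f"trait column {trait!r} not in sample metadata")
    df = pd.DataFrame(index=gm.samples)
    for name, vi in dosage_cols.items():
        dos = gm.dosage[:, vi].astype(float)
        dos[gm.dosage[:, vi] == MISSING] = np.nan
        df[name] = dos
    df["__y__"] = pd.to_numeric(meta[trait], errors="coerce").to_numpy()
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate column {cov!r} not in sample metadata")
        df[cov] = meta[cov].to_numpy()
    return df.dropna()


def _drop_constant_covariates(df: pd.DataFrame, covariates: tuple[str, ...], notes: list[str]) -> list[str]:
    kept = []
    for cov in covariates:
        if df[cov].nunique() < 2:
            notes.append(f"covariate {cov!r} is constant in the analysed subset; dropped")
            logger.info(notes[-1])
        else:
            kept.append(cov)
    return kept


def associate_variant(
    gm: GenotypeMatrix,
    variant_id: str,
    trait: str,
    covariates: tuple[str, ...] = ("sex", "batch"),
    log_transform: bool = False,
) -> AssociationResult:
    """Additive single-locus association: y ~ 1 + dosage + covariates.

    Complete-case over genotype, trait and covariates; constant covariates
    are dropped with a note.  The reported focus term is the per-copy dosage
    effect.  ``log_transform`` fits log(y) instead (offered, not endorsed,
    for right-skewed traits).
    """
    vi = gm.find_variant(variant_id)
    df = _complete_case_frame(gm, {"dosage": vi}, trait, covariates)
    if df["dosage"].nunique() < 2:
        raise ValueError(f"variant {variant_id!r} has constant dosage in complete cases")
    notes: list[str] = []
    kept = _drop_constant_covariates(df, covariates, notes)
    y = df["__y__"].to_numpy()
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform needs strictly positive trait values")
        y = np.log(y)
    res = ols_fit(y, df[["dosage"] + kept], focus="dosage")
    res.notes.extend(notes)
    res.formula = f"{trait} ~ " + " + ".join(["1", "dosage"] + kept)
    return res


def interaction_association(
    gm: GenotypeMatrix,
    variant_id_1: str,
    variant_id_2: str,
    trait: str,
    covariates: tuple[str, ...] = ("sex", "batch"),
) -> AssociationResult:
    """Two-locus model with epistasis: y ~ 1 + g1 + g2 + g1·g2 + covariates.

    The focus term is the product (interaction) coefficient; a degenerate
    genotype distribution that makes the product collinear with the main
    effects is an error.
    """
    v1 = gm.find_variant(variant_id_1)
    v2 = gm.find_variant(variant_id_2)
    df = _complete_case_frame(gm, {"g1": v1, "g2": v2}, trait, covariates)
    for name, vid in (("g1", variant_id_1), ("g2", variant_id_2)):
        if df[name].nunique() < 2:
            raise ValueError(f"variant {vid!r} has constant dosage in complete cases")
    df["g1:g2"] = df["g1"] * df["g2"]
    notes: list[str] = []
    kept = _drop_constant_covariates(df, covariates, notes)
    res = ols_fit(df["__y__"].to_numpy(), df[["g1", "g2", "g1:g2"] + kept], focus="g1:g2")
    res.notes.extend(notes)
    res.formula = f"{trait} ~ " + " + ".join(["1", "g1", "g2", "g1:g2"] + kept)
    return res
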