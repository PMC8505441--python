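"""Characterizing missingness: pattern, flux, and mechanism probes.

The response indicator R (1 = observed) is the object of every diagnostic
here: influx/outflux coefficients summarize how one variable's missing
(resp. observed) cells pair with other variables' observed (resp. missing)
cells; the monotone index quantifies how far a pattern is from perfect
nesting; and the comorbidity-PCA association probes whether missingness
tracks a patient's disease burden (the signature of an informative,
not-at-random mechanism).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from labmi.tables import BLOCKS, LabTable


def response_indicator(table: LabTable, blocks: str = "pre") -> pd.DataFrame:
    """Build the n x p 0/1 response indicator for a block selection.

    ``blocks`` is ``"pre"``, ``"post"``, or ``"both"``; with ``"both"`` the
    columns are ``analyte__block`` strings so each (analyte, block) pair is
    one variable.
    """
    if blocks in BLOCKS:
        frame = table.block(blocks)
        cols = list(frame.columns)
    elif blocks == "both":
        frame = table.data
        cols = [f"{a}__{b}" for a, b in frame.columns]
    else:
        raise ValueError(f"blocks must be one of {BLOCKS + ('both',)}")
    r = (~frame.isna()).astype(np.int64)
    r.columns = cols
    return r


@dataclass
class FluxResult:
    """Per-variable influx/outflux with explicit undefined flags.

    ``influx[j]`` is the number of (subject, variable-pair) combinations
    with variable j missing and the other variable observed, divided by the
    total number of observed cells; ``outflux[j]`` swaps the roles and
    divides by the total number of missing cells.  A zero denominator makes
    the coefficient undefined (NaN with the flag cleared) rather than 0 or
    1, so degenerate variables are never silently ranked.
    """

    table: pd.DataFrame  # columns: influx, outflux, pct_missing,
    #                      influx_defined, outflux_defined

    @property
    def influx(self) -> pd.Series:
        return self.table["influx"]

    @property
    def outflux(self) -> pd.Series:
        return self.table["outflux"]


def flux_coefficients(R: pd.DataFrame) -> FluxResult:
    """Influx and outflux coefficients of a response indicator."""
    if R.shape[1] < 2:
        raise ValueError("flux coefficients require at least 2 variables")
    M = R.to_numpy(dtype=float)
    n, p = M.shape
    row_obs = M.sum(axis=1)          # observed cells per subject
    row_mis = p - row_obs
    tot_obs = float(row_obs.sum())
    tot_mis = float(n * p - tot_obs)

    i_num = ((1.0 - M) * row_obs[:, None]).sum(axis=0)
    o_num = (M * row_mis[:, None]).sum(axis=0)
    influx = i_num / tot_obs if tot_obs > 0 else np.full(p, np.nan)
    outflux = o_num / tot_mis if tot_mis > 0 else np.full(p, np.nan)

    out = pd.DataFrame(
        {
            "influx": influx,
            "outflux": outflux,
            "pct_missing": 100.0 * (1.0 - M.mean(axis=0)),
            "influx_defined": tot_obs > 0,
            "outflux_defined": tot_mis > 0,
        },
        index=R.columns,
    )
    return FluxResult(out)


def monotone_index(R: pd.DataFrame) -> tuple[float, list]:
    """Fraction of adjacent-pair cells violating monotone nesting.

    Variables are sorted by missingness ascending (stable); for each subject
    and each adjacent pair in that order, "missing the lower-missingness
    variable but observing the higher-missingness one" is a violation.
    0 means a perfectly nested (monotone) pattern; an MCAR mask at rate q on
    two variables scores about q(1-q).
    """
    if R.shape[1] < 2:
        raise ValueError("monotone index requires at least 2 variables")
    M = R.to_numpy(dtype=np.int64)
    n, p = M.shape
    miss = (1 - M).sum(axis=0)
    order = np.argsort(miss, kind="stable")
    S = M[:, order]
    violations = int(((S[:, :-1] == 0) & (S[:, 1:] == 1)).sum())
    evaluated = n * (p - 1)
    return violations / evaluated, [R.columns[i] for i in order]


def comorbidity_pca(comorbidity: pd.DataFrame, n_components: int = 5,
                    scale: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the (centered, by default unscaled) binary
    comorbidity table.

    Constant columns are excluded with a warning (they carry no variance).
    Components are ordered by explained variance; each component's
    largest-magnitude loading is made positive so signs are reproducible.
    Returns (scores indexed like the input, explained variance ratios).
    """
    X = comorbidity.astype(float)
    const = X.columns[X.nunique(dropna=False) <= 1]
    if len(const) > 0:
        warnings.warn(f"excluding constant comorbidity columns {list(const)}",
                      stacklevel=2)
        X = X.drop(columns=const)
    if X.shape[1] < n_components:
        raise ValueError(
            f"need at least {n_components} non-constant columns, have {X.shape[1]}")
    vals = X.to_numpy()
    if scale:
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(vals)
    # sign convention: largest-|loading| of each component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1.0
            scores[:, k] *= -1.0
    score_df = pd.DataFrame(
        scores, index=comorbidity.index,
        columns=[f"Dim{k + 1}" for k in range(n_components)],
    )
    return score_df, pca.explained_variance_ratio_


def missingness_pc_association(R: pd.DataFrame, scores: pd.DataFrame
                               ) -> pd.DataFrame:
    """Welch t-test of PC scores between observed and missing subjects.

    For every (variable, component) pair the subjects with r=1 and r=0 are
    compared with an unequal-variance two-sided t-test; ``neg_log10_p`` is
    reported for plotting.  Entries of R that are NaN are excluded from both
    groups (used when the indicator covers only a sub-universe, e.g. a
    holdout mask over originally observed cells).  A group smaller than 2
    leaves the association undefined (flagged).
    """
    scores = scores.loc[R.index]
    rows = []
    for var in R.columns:
        r = R[var].to_numpy(dtype=float)
        valid = ~np.isnan(r)
        for comp in scores.columns:
            s = scores[comp].to_numpy(dtype=float)
            obs = s[valid & (r == 1)]
            mis = s[valid & (r == 0)]
            if len(obs) < 2 or len(mis) < 2:
                rows.append((var, comp, np.nan, np.nan, np.nan,
                             np.nan, np.nan, False))
                continue
            t, p = stats.ttest_ind(obs, mis, equal_var=False)
            rows.append((var, comp, float(t), float(p),
                         float(-np.log10(max(p, np.finfo(float).tiny))),
                         float(obs.mean()), float(mis.mean()), True))
    return pd.DataFrame(
        rows, columns=["variable", "component", "t", "p", "neg_log10_p",
                       "mean_observed", "mean_missing", "defined"],
    )


def margin_pair_summary(table: LabTable, var_a, var_b) -> dict:
    """The numbers behind a margin plot for two variables.

    Variables are ``(analyte, block)`` tuples or ``"analyte__block"``
    strings.  Returns the median/IQR of each variable split by the other's
    missingness status plus the 2x2 observed/missing counts; empty strata
    yield NaN statistics with a flag.
    """
    def _key(v):
        if isinstance(v, str) and "__" in v:
            a, b = v.rsplit("__", 1)
            return (a, b)
        return tuple(v)

    ka, kb = _key(var_a), _key(var_b)
    for k in (ka, kb):
        if k not in table.data.columns:
            raise KeyError(f"variable {k} not in table")
    a = table.data[ka].to_numpy(dtype=float)
    b = table.data[kb].to_numpy(dtype=float)
    a_obs, b_obs = ~np.isnan(a), ~np.isnan(b)

    def _stats(values: np.ndarray) -> dict:
        if values.size == 0:
            return {"median": np.nan, "iqr": np.nan, "n": 0, "defined": False}
        q1, q3 = np.percentile(values, [25, 75])
        return {"median": float(np.median(values)), "iqr": float(q3 - q1),
                "n": int(values.size), "defined": True}

    return {
        "var_a": ka,
        "var_b": kb,
        "a_given_b_observed": _stats(a[a_obs & b_obs]),
        "a_given_b_missing": _stats(a[a_obs & ~b_obs]),
        "b_given_a_observed": _stats(b[b_obs & a_obs]),
        "b_given_a_missing": _stats(b[b_obs & ~a_obs]),
        "counts": {
            "both_observed": int((a_obs & b_obs).sum()),
            "a_only": int((a_obs & ~b_obs).sum()),
            "b_only": int((~a_obs & b_obs).sum()),
            "both_missing": int((~a_obs & ~b_obs).sum()),
        },
    }
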