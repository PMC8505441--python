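"""Multiple-imputation drivers: monotone and FCS procedures, the univariate
auxiliary-variable model, repeated MI, and Rubin pooling.

Two methods are orchestrated over a :class:`~labmi.tables.LabTable`:

* ``pmm`` — cross-sectional predictive mean matching, one (analyte, block)
  column at a time, predictors = the other columns of the wide table;
* ``multilevel`` — the two-level random-intercept model, one analyte at a
  time on its stacked pre/post rows, predictors = intercept, TIME and the
  same-block values of the other analytes; the shared patient intercept is
  what lets an observed post value inform an imputed pre value.

Both methods run under either a single ordered *monotone* pass (each target
conditioned on already-complete variables) or iterated *FCS* sweeps (each
incomplete variable revisited conditional on the current completed data).

Randomness: every (sweep, variable) imputation event gets its own stream
derived from a root drawn once from the caller's generator, so a run is
reproducible in isolation and FCS with one sweep on a single incomplete
variable coincides exactly with the monotone pass under the same seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from labmi.core import GibbsPriors, pan_impute, pmm_impute
from labmi.tables import BLOCKS, LabTable

METHODS = ("pmm", "multilevel")
PROCEDURES = ("monotone", "fcs")


@dataclass
class ImputationSpec:
    """Full configuration of one imputation run."""

    method: str = "pmm"
    procedure: str = "fcs"
    predictors: dict | None = None  # per-target predictor restriction
    donors: int = 5
    fcs_iterations: int = 20
    gibbs_sweeps: int = 200
    gibbs_burn: int = 100
    m: int = 5
    seed: int = 0
    ridge: float = 1e-5
    priors: GibbsPriors = field(default_factory=GibbsPriors)

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.procedure not in PROCEDURES:
            raise ValueError(
                f"unknown procedure {self.procedure!r}; expected {PROCEDURES}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.fcs_iterations < 1:
            raise ValueError("fcs_iterations must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")


@dataclass
class ImputedSets:
    """m completed copies of a LabTable plus provenance."""

    tables: list
    spec: ImputationSpec
    child_keys: list
    traces: list | None = None

    def __len__(self) -> int:
        return len(self.tables)


@dataclass
class PooledEstimate:
    """Rubin's-rules pooling of m per-set estimates."""

    q_bar: float
    within: float
    between: float
    total: float
    df: float
    m: int


def sort_by_missingness(R: pd.DataFrame) -> list:
    """Variables ascending by missing count; ties keep column order."""
    if R.shape[1] < 1:
        raise ValueError("need at least one variable")
    miss = (1 - R.to_numpy(dtype=np.int64)).sum(axis=0)
    order = np.argsort(miss, kind="stable")
    return [R.columns[i] for i in order]


# ---------------------------------------------------------------------------
# internal working representation


class _Work:
    """Numpy view of a LabTable used by the imputation inner loops."""

    def __init__(self, table: LabTable):
        self.table = table
        self.columns = list(table.data.columns)
        self.col_idx = {c: i for i, c in enumerate(self.columns)}
        self.analytes = table.analytes
        self.Y = table.data.to_numpy(dtype=float).copy()
        self.orig_missing = np.isnan(self.Y)
        self.n = self.Y.shape[0]

    def finish(self) -> LabTable:
        data = pd.DataFrame(self.Y, index=self.table.data.index,
                            columns=self.table.data.columns)
        return self.table.with_data(data)

    # column targets (pmm) -------------------------------------------------

    def incomplete_columns(self) -> list:
        return [c for c in self.columns
                if self.orig_missing[:, self.col_idx[c]].any()]

    def impute_column_pmm(self, col, pred_cols: Sequence, spec: ImputationSpec,
                          rng: np.random.Generator) -> None:
        j = self.col_idx[col]
        mis = self.orig_missing[:, j]
        obs = ~mis
        if not obs.any():
            raise ValueError(f"variable {col} has zero observed values")
        pidx = [self.col_idx[c] for c in pred_cols]
        X = np.column_stack([np.ones(self.n), self.Y[:, pidx]]) \
            if pidx else np.ones((self.n, 1))
        self.Y[mis, j] = pmm_impute(
            self.Y[obs, j], X[obs], X[mis],
            donors=spec.donors, rng=rng, ridge=spec.ridge)

    # analyte targets (multilevel) ----------------------------------------

    def incomplete_analytes(self) -> list:
        out = []
        for a in self.analytes:
            cols = [self.col_idx[(a, b)] for b in BLOCKS
                    if (a, b) in self.col_idx]
            if self.orig_missing[:, cols].any():
                out.append(a)
        return out

    def _long_stack(self, analyte, pred_analytes: Sequence):
        """Stack pre/post rows of one analyte with same-block predictors."""
        blocks = [b for b in BLOCKS if (analyte, b) in self.col_idx]
        y_parts, X_parts = [], []
        for t, b in enumerate(blocks):
            j = self.col_idx[(analyte, b)]
            y = self.Y[:, j].copy()
            y[self.orig_missing[:, j]] = np.nan
            y_parts.append(y)
            preds = [self.Y[:, self.col_idx[(p, b)]] for p in pred_analytes
                     if (p, b) in self.col_idx]
            X_parts.append(np.column_stack(
                [np.ones(self.n), np.full(self.n, float(t))] + preds))
        y_long = np.concatenate(y_parts)
        X_long = np.vstack(X_parts)
        clusters = np.tile(np.arange(self.n), len(blocks))
        return y_long, X_long, clusters, blocks

    def impute_analyte_multilevel(self, analyte, pred_analytes: Sequence,
                                  spec: ImputationSpec,
                                  rng: np.random.Generator) -> None:
        y, X, clusters, blocks = self._long_stack(analyte, pred_analytes)
        if np.isnan(y).all():
            raise ValueError(f"variable {analyte!r} has zero observed values")
        completed, _ = pan_impute(
            y, X, clusters, n_clusters=self.n, n_sweeps=spec.gibbs_sweeps,
            rng=rng, priors=spec.priors, ridge=spec.ridge)
        for t, b in enumerate(blocks):
            j = self.col_idx[(analyte, b)]
            mis = self.orig_missing[:, j]
            self.Y[mis, j] = completed[t * self.n:(t + 1) * self.n][mis]


def _event_rng(root: int, sweep: int, j: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([root, sweep, j]))


def _root(rng: np.random.Generator | None) -> int:
    if rng is None:
        rng = np.random.default_rng()
    return int(rng.integers(0, 2 ** 63 - 1))


def _restrict(preds: list, spec: ImputationSpec, target) -> list:
    if spec.predictors is None:
        return preds
    allowed = spec.predictors.get(target)
    if allowed is None:
        return preds
    return [p for p in preds if p in set(allowed)]


# ---------------------------------------------------------------------------
# procedures


def impute_monotone(table: LabTable, spec: ImputationSpec,
                    rng: np.random.Generator | None = None) -> LabTable:
    """Single ordered pass: targets sorted ascending by missingness, each
    conditioned on initially-complete variables and previously imputed ones.
    """
    spec.validate()
    root = _root(rng)
    work = _Work(table)

    if spec.method == "pmm":
        targets = work.incomplete_columns()
        miss = {c: int(work.orig_missing[:, work.col_idx[c]].sum())
                for c in targets}
        targets.sort(key=lambda c: miss[c])  # stable: ties keep column order
        done = [c for c in work.columns if c not in set(targets)]
        for col in targets:
            # cross-sectional benchmark: predictors from the same time
            # block only (the longitudinal link is the multilevel model's)
            preds = _restrict([c for c in done if c[1] == col[1]], spec, col)
            work.impute_column_pmm(col, preds, spec,
                                   _event_rng(root, 1, work.col_idx[col]))
            done.append(col)
    else:
        targets = work.incomplete_analytes()
        a_miss = {}
        for a in targets:
            cols = [work.col_idx[(a, b)] for b in BLOCKS if (a, b) in work.col_idx]
            a_miss[a] = int(work.orig_missing[:, cols].sum())
        targets.sort(key=lambda a: a_miss[a])
        done = [a for a in work.analytes if a not in set(targets)]
        for a in targets:
            preds = _restrict(list(done), spec, a)
            work.impute_analyte_multilevel(
                a, preds, spec, _event_rng(root, 1, work.analytes.index(a)))
            done.append(a)
    return work.finish()


def impute_fcs(table: LabTable, spec: ImputationSpec,
               rng: np.random.Generator | None = None
               ) -> tuple[LabTable, pd.DataFrame]:
    """Fully conditional specification: random starting imputations, then
    ``fcs_iterations`` sweeps revisiting every incomplete variable in column
    order conditional on the current completed data.  Returns the completed
    table and the per-sweep chain trace (imputed-cell mean and SD per
    variable), the convergence diagnostic of the chained-equations sampler.
    """
    spec.validate()
    root = _root(rng)
    work = _Work(table)
    trace_rows: list[tuple] = []

    # starting imputations: uniform draws from each variable's observed values
    for c in work.incomplete_columns():
        j = work.col_idx[c]
        mis = work.orig_missing[:, j]
        obs_vals = work.Y[~mis, j]
        if obs_vals.size == 0:
            raise ValueError(f"variable {c} has zero observed values")
        r = _event_rng(root, 0, j)
        work.Y[mis, j] = r.choice(obs_vals, size=int(mis.sum()), replace=True)

    if spec.method == "pmm":
        targets = work.incomplete_columns()
        for t in range(1, spec.fcs_iterations + 1):
            for col in targets:
                preds = _restrict(
                    [c for c in work.columns if c != col and c[1] == col[1]],
                    spec, col)
                work.impute_column_pmm(col, preds, spec,
                                       _event_rng(root, t, work.col_idx[col]))
            for col in targets:
                j = work.col_idx[col]
                vals = work.Y[work.orig_missing[:, j], j]
                trace_rows.append((t, f"{col[0]}__{col[1]}",
                                   float(vals.mean()),
                                   float(vals.std(ddof=1)) if vals.size > 1 else 0.0))
    else:
        targets = work.incomplete_analytes()
        for t in range(1, spec.fcs_iterations + 1):
            for a in targets:
                preds = _restrict([p for p in work.analytes if p != a], spec, a)
                work.impute_analyte_multilevel(
                    a, preds, spec, _event_rng(root, t, work.analytes.index(a)))
            for a in targets:
                cols = [work.col_idx[(a, b)] for b in BLOCKS
                        if (a, b) in work.col_idx]
                vals = np.concatenate(
                    [work.Y[work.orig_missing[:, j], j] for j in cols])
                trace_rows.append((t, a, float(vals.mean()),
                                   float(vals.std(ddof=1)) if vals.size > 1 else 0.0))

    trace = pd.DataFrame(trace_rows,
                         columns=["iteration", "variable", "mean", "sd"])
    return work.finish(), trace


def impute_univariate_auxiliary(table: LabTable, target,
                                pc_scores: pd.DataFrame | None,
                                spec: ImputationSpec,
                                rng: np.random.Generator | None = None
                                ) -> LabTable:
    """Univariate two-level imputation of one analyte, optionally with
    comorbidity-PC auxiliaries.

    The model has fixed effects (intercept, TIME, PC1..PCk when
    ``pc_scores`` is given) and a patient random intercept; missing cells
    are drawn from the posterior predictive as in :func:`pan_impute`.
    Passing ``pc_scores=None`` is the "without auxiliary variables" arm.
    """
    spec.validate()
    if target not in table.analytes:
        raise KeyError(f"unknown target analyte {target!r}")
    root = _root(rng)
    work = _Work(table)
    cols = [work.col_idx[(target, b)] for b in BLOCKS
            if (target, b) in work.col_idx]
    if not work.orig_missing[:, cols].any():
        return table.copy()
    if not (~work.orig_missing[:, cols]).any():
        raise ValueError(f"target {target!r} has zero observed values")

    y, X, clusters, blocks = work._long_stack(target, [])
    if pc_scores is not None:
        if pc_scores.shape[1] != 5:
            warnings.warn(
                f"{pc_scores.shape[1]} auxiliary components supplied "
                "(the usual choice is 5)", stacklevel=2)
        S = pc_scores.loc[table.data.index].to_numpy(dtype=float)
        X = np.hstack([X, np.vstack([S] * len(blocks))])

    completed, _ = pan_impute(
        y, X, clusters, n_clusters=work.n, n_sweeps=spec.gibbs_sweeps,
        rng=_event_rng(root, 1, 0), priors=spec.priors, ridge=spec.ridge)
    for t, b in enumerate(blocks):
        j = work.col_idx[(target, b)]
        mis = work.orig_missing[:, j]
        work.Y[mis, j] = completed[t * work.n:(t + 1) * work.n][mis]
    return work.finish()


# ---------------------------------------------------------------------------
# repeated MI and pooling


def _child_rng(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(k)]))


def run_repeated_mi(table: LabTable, spec: ImputationSpec) -> ImputedSets:
    """Produce m completed sets, one per child seed of ``spec.seed``.

    Child streams are keyed (seed, set index), so any single set can be
    regenerated in isolation; observed cells are identical across sets by
    construction.
    """
    spec.validate()
    tables, traces, keys = [], [], []
    for k in range(spec.m):
        rng = _child_rng(spec.seed, k)
        if spec.procedure == "monotone":
            tables.append(impute_monotone(table, spec, rng))
            traces.append(None)
        else:
            completed, trace = impute_fcs(table, spec, rng)
            tables.append(completed)
            traces.append(trace)
        keys.append((spec.seed, k))
    has_trace = any(t is not None for t in traces)
    return ImputedSets(tables=tables, spec=spec, child_keys=keys,
                       traces=traces if has_trace else None)


def run_repeated_univariate(table: LabTable, target,
                            pc_scores: pd.DataFrame | None,
                            spec: ImputationSpec) -> ImputedSets:
    """Repeated univariate auxiliary-model MI (the case-study arm)."""
    spec.validate()
    tables, keys = [], []
    for k in range(spec.m):
        rng = _child_rng(spec.seed, k)
        tables.append(impute_univariate_auxiliary(table, target, pc_scores,
                                                  spec, rng))
        keys.append((spec.seed, k))
    return ImputedSets(tables=tables, spec=spec, child_keys=keys)


def pool_rubin(estimates: Sequence[float],
               within_vars: Sequence[float]) -> PooledEstimate:
    """Combine m per-set estimates by Rubin's rules.

    Q-bar = mean of the estimates, W = mean within-imputation variance,
    B = sample variance of the estimates, T = W + (1 + 1/m) B, and the
    large-sample degrees of freedom (m - 1)(1 + W / ((1 + 1/m) B))^2.
    """
    est = np.asarray(estimates, dtype=float)
    win = np.asarray(within_vars, dtype=float)
    if len(est) != len(win):
        raise ValueError("estimates and within_vars must have equal length")
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 for the between variance")
    q_bar = float(est.mean())
    w = float(win.mean())
    b = float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        with np.errstate(over="ignore"):
            df = (m - 1) * np.square(
                np.float64(1.0 + w / ((1.0 + 1.0 / m) * b)))
    else:
        df = np.inf
    return PooledEstimate(q_bar=q_bar, within=w, between=b, total=t,
                          df=float(df), m=m)
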