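"""The benchmarking harness: holdout policies, error metrics, uncertainty
propagation, and algorithm comparison.

Two holdout policies mimic the two missingness scenarios seen in EHR data:

* HV — hold out random observed *values* per variable (arbitrary /
  MAR-like missingness);
* HC — hold out entire *complete cases* (monotone, informative
  missingness: the held-out patients are exactly those whose utilization
  kept them fully observed).

Errors are summarized as nRMSE (RMSE over the holdouts divided by the
analyte's observed-data SD), coverage rate and average width of per-holdout
intervals over the m imputations, with running mean/SE checkpoints tracking
how uncertainty propagates as imputations accumulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from labmi.procedures import ImputationSpec, ImputedSets, run_repeated_mi
from labmi.synthetic import impose_missingness, generate_complete_cohort, preset
from labmi.tables import LabTable

POLICIES = ("HV", "HC")


@dataclass
class HoldoutMask:
    """Cells withheld under a policy, with their true values."""

    policy: str
    cells: list          # (patient, analyte, block) triples
    truth: np.ndarray
    n_requested: int
    seed: int | None = None

    def by_analyte(self) -> dict:
        """Indices into ``cells`` grouped per analyte."""
        out: dict = {}
        for i, (_, a, _) in enumerate(self.cells):
            out.setdefault(a, []).append(i)
        return out


def holdout_values(table: LabTable, n: int = 50,
                   rng: np.random.Generator | None = None
                   ) -> tuple[LabTable, HoldoutMask]:
    """HV policy: per analyte, mask min(n, observed) random pre-block cells.

    Holdouts come solely from observed data, so the masked-cell set is
    disjoint from the originally missing cells.  Analytes with fewer
    observed cells than requested are reduced with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n < 0:
        raise ValueError("n must be >= 0")
    cells: list = []
    pre = table.block("pre")
    for a in pre.columns:
        obs_idx = pre.index[pre[a].notna()]
        if len(obs_idx) == 0:
            raise ValueError(f"analyte {a!r} has no observed pre-block cells")
        take = min(n, len(obs_idx))
        if take < n:
            warnings.warn(f"analyte {a!r}: only {len(obs_idx)} observed cells; "
                          f"holding out {take} instead of {n}", stacklevel=2)
        picked = rng.choice(len(obs_idx), size=take, replace=False)
        cells.extend((obs_idx[i], a, "pre") for i in picked)
    truth = table.get_cells(cells) if cells else np.empty(0)
    masked = table.set_cells(cells, np.full(len(cells), np.nan)) if cells \
        else table.copy()
    return masked, HoldoutMask(policy="HV", cells=cells, truth=truth,
                               n_requested=n)


def complete_cases(table: LabTable) -> pd.Index:
    """Patients with every retained analyte observed in the pre block."""
    return table.block("pre").dropna().index


def holdout_complete_cases(table: LabTable, n: int = 50,
                           rng: np.random.Generator | None = None
                           ) -> tuple[LabTable, HoldoutMask]:
    """HC policy: mask all pre-block cells of n random complete cases.

    Because the held-out patients were complete, the monotone connection
    among the remaining data is untouched.  Fewer than n complete cases is
    an error reporting the available count.
    """
    if rng is None:
        rng = np.random.default_rng()
    cc = complete_cases(table)
    if len(cc) < n:
        raise ValueError(
            f"only {len(cc)} complete cases available, {n} requested")
    picked = cc[np.sort(rng.choice(len(cc), size=n, replace=False))]
    cells = [(pid, a, "pre") for pid in picked for a in table.analytes]
    truth = table.get_cells(cells)
    masked = table.set_cells(cells, np.full(len(cells), np.nan))
    return masked, HoldoutMask(policy="HC", cells=cells, truth=truth,
                               n_requested=n)


# ---------------------------------------------------------------------------
# metrics


def nrmse(imputed, truth, delta: float) -> float:
    """Root-mean-square error normalized by the scale ``delta``
    (conventionally the analyte's observed-data SD)."""
    imputed = np.asarray(imputed, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if len(imputed) != len(truth) or len(truth) == 0:
        raise ValueError("imputed and truth must have equal, nonzero length")
    if not delta > 0:
        raise ValueError("delta must be > 0")
    return float(np.sqrt(np.mean((imputed - truth) ** 2)) / delta)


def _cell_matrix(sets: ImputedSets, mask: HoldoutMask) -> np.ndarray:
    """m x n_holdout matrix of imputed values at the masked cells."""
    return np.vstack([t.get_cells(mask.cells) for t in sets.tables])


def coverage_and_width(sets: ImputedSets, mask: HoldoutMask,
                       level: float = 0.95) -> pd.DataFrame:
    """Per-analyte coverage rate and average width of per-holdout intervals.

    For each held-out cell the m imputed values give an interval
    mean +/- t(level, m-1) * SD; the SD of the m values (not the SD of
    their mean) is the spread of plausible values for that cell, which is
    what a calibrated imputer should cover the truth with at the nominal
    rate.  CR is the fraction of an analyte's holdouts whose interval
    contains the truth; AW is the mean interval width.  A zero-width
    interval contains the truth iff it equals it to 1e-12.
    """
    m = len(sets)
    if m < 2:
        raise ValueError("coverage needs m >= 2 imputed sets")
    vals = _cell_matrix(sets, mask)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    half = stats.t.ppf(0.5 + level / 2.0, m - 1) * sd
    contains = np.abs(mask.truth - mean) <= half + 1e-12
    rows = []
    for a, idx in mask.by_analyte().items():
        idx = np.asarray(idx)
        rows.append((a, float(contains[idx].mean()),
                     float((2.0 * half[idx]).mean()), len(idx)))
    return pd.DataFrame(rows, columns=["analyte", "cr", "aw", "n_holdouts"])


def uncertainty_propagation(per_repeat_nrmse,
                            checkpoints=(5, 10, 20, 30, 40, 50)
                            ) -> pd.DataFrame:
    """Running mean and SE of nRMSE at the given repeat-count checkpoints."""
    x = np.asarray(per_repeat_nrmse, dtype=float)
    rows = []
    for c in checkpoints:
        if c > len(x):
            warnings.warn(f"checkpoint {c} exceeds the {len(x)} available "
                          "repeats; truncated", stacklevel=2)
            break
        sub = x[:c]
        se = float(sub.std(ddof=1) / np.sqrt(c)) if c > 1 else np.nan
        rows.append((c, float(sub.mean()), se))
    return pd.DataFrame(rows, columns=["checkpoint", "mean", "se"])


def compare_algorithms(nrmse_a, nrmse_b, n_tests: int,
                       alpha: float = 0.05) -> dict:
    """Compare two per-repeat nRMSE vectors the way the benchmark does:
    Levene (center=mean) for equal variance, Shapiro-Wilk on the paired
    difference for normality, and an unpaired two-sided t-test whose raw p
    is Bonferroni-thresholded at alpha / n_tests.
    """
    a = np.asarray(nrmse_a, dtype=float)
    b = np.asarray(nrmse_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 repeats per arm")
    out: dict = {"n_tests": int(n_tests), "alpha": float(alpha),
                 "threshold": float(alpha / n_tests)}
    if a.std(ddof=1) > 0 or b.std(ddof=1) > 0:
        out["levene_p"] = float(stats.levene(a, b, center="mean").pvalue)
    else:
        out["levene_p"] = np.nan
    if len(a) == len(b):
        diff = a - b
        out["shapiro_p"] = (float(stats.shapiro(diff).pvalue)
                            if np.ptp(diff) > 0 else np.nan)
    else:
        out["shapiro_p"] = np.nan
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            out["t"], out["p"] = 0.0, 1.0
        else:
            out["t"], out["p"] = np.nan, np.nan
            out["defined"] = False
            out["significant"] = False
            return out
    else:
        t, p = stats.ttest_ind(a, b)
        out["t"], out["p"] = float(t), float(p)
    out["defined"] = True
    out["significant"] = bool(out["p"] < out["threshold"])
    return out


def over_imputation_table(sets: ImputedSets, mask: HoldoutMask
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-holdout truth vs imputed mean/SE, plus the Pearson correlation
    between truth and imputed means — the data behind an over-imputation
    scatter diagnostic."""
    m = len(sets)
    if m < 2:
        raise ValueError("over-imputation needs m >= 2 sets")
    vals = _cell_matrix(sets, mask)
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(m)
    per = pd.DataFrame({
        "patient": [c[0] for c in mask.cells],
        "analyte": [c[1] for c in mask.cells],
        "truth": mask.truth,
        "imputed_mean": mean,
        "imputed_se": se,
    })
    summary: dict = {"n_holdouts": len(mask.cells), "defined": False,
                     "r": np.nan, "p": np.nan}
    if len(mask.cells) >= 3 and np.ptp(mean) > 0 and np.ptp(mask.truth) > 0:
        r, p = stats.pearsonr(mask.truth, mean)
        summary.update(r=float(r), p=float(p), defined=True)
    return per, summary


def case_study_metrics(sets: ImputedSets, mask: HoldoutMask,
                       level: float = 0.95) -> dict:
    """Per-set correlation metrics for a single-target case study.

    R is computed per completed set (truth vs that set's imputations at the
    held-out cells) and averaged across the m sets; SE = SD(R)/sqrt(m) and
    CV = SD(R)/mean(R).  Each per-set R also gets a Fisher-z confidence
    interval; CR is the proportion of those intervals containing the
    average R and AW their mean width.
    """
    m = len(sets)
    if m < 2:
        raise ValueError("case-study metrics need m >= 2 sets")
    n_holdouts = len(mask.cells)
    if n_holdouts < 3:
        raise ValueError("need at least 3 holdouts")
    vals = _cell_matrix(sets, mask)
    rs = np.array([stats.pearsonr(mask.truth, vals[k])[0] for k in range(m)])
    mean_r = float(rs.mean())
    sd_r = float(rs.std(ddof=1))
    out = {"m": m, "n_holdouts": n_holdouts, "average_r": mean_r,
           "se_r": sd_r / np.sqrt(m),
           "cv_r": sd_r / mean_r if mean_r != 0 else np.nan,
           "cv_defined": mean_r != 0}
    z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
    zc = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n_holdouts - 3)
    lo, hi = np.tanh(z - zc), np.tanh(z + zc)
    out["cr"] = float(((lo <= mean_r) & (mean_r <= hi)).mean())
    out["aw"] = float((hi - lo).mean())
    return out


# ---------------------------------------------------------------------------
# benchmark driver


def _delta_per_analyte(masked: LabTable) -> dict:
    """nRMSE scale: SD of each analyte's observed (non-held-out) pre values."""
    pre = masked.block("pre")
    out = {}
    for a in pre.columns:
        obs = pre[a].dropna().to_numpy()
        out[a] = float(obs.std(ddof=1)) if len(obs) > 1 else np.nan
    return out


def run_benchmark(preset_name: str = "gnsis-like", n_patients: int = 2000,
                  n_analytes: int = 12, seeds=range(20), m: int = 20,
                  hv_holdouts: int = 20, hc_cases: int = 50,
                  runs=(("HV", "pmm", "fcs"),
                        ("HV", "multilevel", "fcs"),
                        ("HV", "multilevel", "monotone"),
                        ("HC", "multilevel", "fcs")),
                  fcs_iterations: int = 5, gibbs_sweeps: int = 20,
                  donors: int = 5, base_seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Holdout-policy x algorithm grid over replicated synthetic cohorts.

    For every replicate seed a fresh preset cohort is generated and masked,
    holdouts are drawn under each policy, each (method, procedure) run
    produces m completed sets, and per-set nRMSE plus per-analyte CR/AW are
    recorded.  Returns (nrmse table, coverage table) in tidy form with an
    ``algorithm`` label like ``"multilevel-fcs"``.
    """
    nrmse_rows, cr_rows = [], []
    for s in seeds:
        ss = np.random.SeedSequence([int(base_seed), int(s)])
        k_cohort, k_hv, k_hc, k_mi = (int(v) for v in ss.generate_state(4) % (2 ** 31))
        cfg, mcfg = preset(preset_name, n_patients=n_patients,
                           n_analytes=n_analytes, seed=k_cohort)
        bundle = impose_missingness(generate_complete_cohort(cfg), mcfg)
        table = bundle.observed_labs

        masks: dict = {}
        masked_tables: dict = {}
        policies = {p for p, _, _ in runs}
        if "HV" in policies:
            masked_tables["HV"], masks["HV"] = holdout_values(
                table, hv_holdouts, np.random.default_rng(k_hv))
        if "HC" in policies:
            n_cc = min(hc_cases, len(complete_cases(table)))
            masked_tables["HC"], masks["HC"] = holdout_complete_cases(
                table, n_cc, np.random.default_rng(k_hc))

        for run_idx, (policy, method, procedure) in enumerate(runs):
            masked = masked_tables[policy]
            mask = masks[policy]
            delta = _delta_per_analyte(masked)
            spec = ImputationSpec(method=method, procedure=procedure,
                                  donors=donors, fcs_iterations=fcs_iterations,
                                  gibbs_sweeps=gibbs_sweeps, m=m,
                                  seed=(k_mi + run_idx) % (2 ** 31))
            sets = run_repeated_mi(masked, spec)
            label = f"{method}-{procedure}"
            groups = mask.by_analyte()
            for k, t in enumerate(sets.tables):
                imp = t.get_cells(mask.cells)
                for a, idx in groups.items():
                    idx = np.asarray(idx)
                    nrmse_rows.append(
                        (int(s), policy, label, a, k,
                         nrmse(imp[idx], mask.truth[idx], delta[a])))
            cw = coverage_and_width(sets, mask)
            for _, row in cw.iterrows():
                cr_rows.append((int(s), policy, label, row["analyte"],
                                row["cr"], row["aw"], int(row["n_holdouts"])))

    nrmse_df = pd.DataFrame(
        nrmse_rows,
        columns=["seed", "policy", "algorithm", "analyte", "repeat", "nrmse"])
    cr_df = pd.DataFrame(
        cr_rows,
        columns=["seed", "policy", "algorithm", "analyte", "cr", "aw",
                 "n_holdouts"])
    return nrmse_df, cr_df
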