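"""Synthetic EHR cohort generator.

Real laboratory cohorts of the kind this package targets (tens of
correlated analytes around a disease index date, 35-75% missingness that is
largely monotone and tied to how sick a patient is) are not publicly
shareable, so every downstream stage is exercised on cohorts drawn from an
explicit generative model:

* analyte values = mean + time effect + patient intercept + panel-correlated
  noise, giving a configurable before/after correlation (the intraclass
  correlation sigma_u^2 / (sigma_u^2 + sigma_e^2)) and a block correlation
  structure within test panels;
* a standard-normal latent *disease burden* per patient that raises
  comorbidity-code prevalence and, optionally, shifts lab values;
* missingness imposed afterwards under MCAR, MAR, or a monotone
  missing-not-at-random mechanism in which a latent utilization score
  (burden plus noise) is thresholded per variable in order of target
  missingness rate, with an arbitrary-missing admixture OR-ed on top.

The arbitrary admixture is correlated within a panel (one provider decision
orders or skips a whole panel), which is what keeps a small minority of
patients fully complete even with many analytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from labmi.tables import BLOCKS, LabTable, from_blocks

MECHANISMS = ("MCAR", "MAR", "MNAR_monotone")
PRESETS = ("gnsis-like", "hf-like")

_PANEL_NAMES = ("cbc", "met", "liv", "lip", "coa", "msc")


@dataclass
class CohortConfig:
    """Generative model for a complete (pre-masking) cohort.

    ``within_panel_corr`` / ``between_panel_corr`` define the latent analyte
    correlation matrix (compound-symmetric within panels); the patient
    intercept is shared between the two time blocks of an analyte, so the
    before/after correlation of a generated analyte is
    ``(patient_intercept_sd^2 + burden_lab_loading^2) / (patient_intercept_sd^2
    + burden_lab_loading^2 + residual_sd^2)``.
    """

    n_patients: int = 500
    panels: Sequence[tuple[str, int]] = (("cbc", 3), ("met", 3))
    within_panel_corr: float = 0.5
    between_panel_corr: float = 0.1
    patient_intercept_sd: float = 1.0
    residual_sd: float = 1.0
    analyte_means: np.ndarray | None = None
    analyte_sds: np.ndarray | None = None
    time_effect: np.ndarray | None = None
    n_comorbidity_codes: int = 20
    burden_loading: float = 1.0
    #: strength of the latent burden's direct effect on lab values (in
    #: latent-SD units).  0 keeps labs independent of burden.
    burden_lab_loading: float = 0.0
    seed: int = 0

    @property
    def n_analytes(self) -> int:
        return int(sum(k for _, k in self.panels))

    @property
    def analyte_names(self) -> list[str]:
        names = []
        for pname, k in self.panels:
            names.extend(f"{pname}{i + 1:02d}" for i in range(k))
        return names

    @property
    def panel_index(self) -> np.ndarray:
        """Panel code (0-based) per analyte, in analyte order."""
        idx = []
        for p, (_, k) in enumerate(self.panels):
            idx.extend([p] * k)
        return np.asarray(idx)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_analytes < 1:
            raise ValueError("at least one analyte is required")
        if self.patient_intercept_sd < 0:
            raise ValueError("patient_intercept_sd must be >= 0")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for name, arr in (("analyte_means", self.analyte_means),
                          ("analyte_sds", self.analyte_sds),
                          ("time_effect", self.time_effect)):
            if arr is not None and len(np.atleast_1d(arr)) != self.n_analytes:
                raise ValueError(f"{name} must have one entry per analyte")
        if self.analyte_sds is not None and np.any(np.atleast_1d(self.analyte_sds) <= 0):
            raise ValueError("analyte_sds must all be > 0")


@dataclass
class MissingnessConfig:
    """How missing cells are imposed on a complete cohort.

    ``target_rates`` are per-analyte missingness fractions for the *pre*
    block (ordering these defines the monotone variable sequence);
    ``post_rates`` default to the pre-block rates.  ``monotone_weight`` is
    the fraction of each target rate produced by the ordered utilization
    threshold; the remainder is an arbitrary Bernoulli admixture whose
    propensity is correlated within a panel with correlation ``panel_corr``.
    ``burden_missing_loading`` links latent burden to the utilization score:
    positive values mean sicker patients are observed more.
    """

    mechanism: str = "MNAR_monotone"
    target_rates: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.5]))
    post_rates: np.ndarray | None = None
    monotone_weight: float = 0.8
    burden_missing_loading: float = 1.0
    panel_corr: float = 0.85
    seed: int = 0

    def validate(self, n_analytes: int) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        rates = np.atleast_1d(np.asarray(self.target_rates, dtype=float))
        if len(rates) != n_analytes:
            raise ValueError("target_rates must have one entry per analyte")
        for arr in (rates,) if self.post_rates is None else (
                rates, np.atleast_1d(np.asarray(self.post_rates, dtype=float))):
            if np.any(arr < 0) or np.any(arr >= 1):
                raise ValueError("target rates must lie in [0, 1)")
        if not 0 <= self.monotone_weight <= 1:
            raise ValueError("monotone_weight must lie in [0, 1]")
        if not 0 <= self.panel_corr < 1:
            raise ValueError("panel_corr must lie in [0, 1)")


@dataclass
class TruthBundle:
    """A synthetic cohort: complete truth, masked observation, covariates."""

    complete_labs: LabTable
    observed_labs: LabTable
    comorbidity: pd.DataFrame
    burden: pd.Series
    index_dates: pd.Series
    cohort_config: CohortConfig | None = None
    missingness_config: MissingnessConfig | None = None


# ---------------------------------------------------------------------------
# complete-cohort generation


def _analyte_correlation(config: CohortConfig) -> np.ndarray:
    p = config.n_analytes
    w, b = config.within_panel_corr, config.between_panel_corr
    panel = config.panel_index
    same_panel = panel[:, None] == panel[None, :]
    corr = np.where(same_panel, w, b)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_complete_cohort(config: CohortConfig) -> TruthBundle:
    """Draw a complete cohort (no masking yet) from the generative model.

    Deterministic given ``config.seed``: the same configuration always
    yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_analytes
    names = config.analyte_names

    corr = _analyte_correlation(config)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "analyte correlation matrix is not positive definite; adjust "
            f"within_panel_corr={config.within_panel_corr} / "
            f"between_panel_corr={config.between_panel_corr}"
        ) from err

    burden = rng.standard_normal(n)
    s_u, s_e, lam = config.patient_intercept_sd, config.residual_sd, config.burden_lab_loading
    scale = np.sqrt(s_u ** 2 + s_e ** 2 + lam ** 2)

    u = s_u * (rng.standard_normal((n, p)) @ chol.T)  # shared patient intercept
    latent = {}
    for t, blk in enumerate(BLOCKS):
        e = s_e * (rng.standard_normal((n, p)) @ chol.T)
        latent[blk] = (lam * burden[:, None] + u + e) / scale

    means = np.zeros(p) if config.analyte_means is None else np.atleast_1d(
        np.asarray(config.analyte_means, dtype=float))
    sds = np.ones(p) if config.analyte_sds is None else np.atleast_1d(
        np.asarray(config.analyte_sds, dtype=float))
    te = np.zeros(p) if config.time_effect is None else np.atleast_1d(
        np.asarray(config.time_effect, dtype=float))

    patients = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")
    blocks = {}
    for t, blk in enumerate(BLOCKS):
        vals = means + te * t + sds * latent[blk]
        blocks[blk] = pd.DataFrame(vals, index=patients, columns=names)
    labs = from_blocks(blocks["pre"], blocks["post"])

    # comorbidity codes: marginal prevalences span 5-50% so that codes below
    # a 20% prevalence filter exist to exercise preprocessing
    k = config.n_comorbidity_codes
    prev = np.linspace(0.05, 0.50, k)
    alpha = logit(prev)
    prob = expit(alpha[None, :] + config.burden_loading * burden[:, None])
    codes = (rng.random((n, k)) < prob).astype(np.int64)
    comorbidity = pd.DataFrame(
        codes, index=patients, columns=[f"DX{j:03d}" for j in range(k)]
    )

    index_dates = pd.Series(
        pd.Timestamp("2016-01-01") + pd.to_timedelta(rng.integers(0, 1461, n), unit="D"),
        index=patients, name="index_date",
    )

    return TruthBundle(
        complete_labs=labs,
        observed_labs=labs.copy(),
        comorbidity=comorbidity,
        burden=pd.Series(burden, index=patients, name="burden"),
        index_dates=index_dates,
        cohort_config=config,
    )


# ---------------------------------------------------------------------------
# missingness imposition


def _monotone_arbitrary_mask(rates: dict[str, np.ndarray], u: np.ndarray,
                             mcfg: MissingnessConfig, panel: np.ndarray,
                             rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Threshold ``u`` per variable in rate order, OR an arbitrary admixture.

    For every (analyte, block) with target rate q, the ``monotone_weight * q``
    patients with the lowest utilization are masked; because all variables
    threshold the same score, a patient missing one variable is missing every
    variable with a higher monotone rate (perfect nesting).  The remaining
    rate is met by a Bernoulli mask correlated within a panel via a Gaussian
    copula, so the realized per-variable rate stays on target while whole
    panels tend to drop together.
    """
    n = len(u)
    order = np.argsort(u, kind="stable")  # ascending utilization
    w, c = mcfg.monotone_weight, mcfg.panel_corr
    masks = {}
    for blk, q in rates.items():
        mono = np.zeros((n, len(q)), dtype=bool)
        for j, qj in enumerate(q):
            k = int(round(w * qj * n))
            if k > 0:
                mono[order[:k], j] = True
        # arbitrary admixture, panel-correlated
        shared = rng.standard_normal((n, panel.max() + 1))
        eps = rng.standard_normal((n, len(q)))
        z = np.sqrt(c) * shared[:, panel] + np.sqrt(1.0 - c) * eps
        q_mono = w * np.asarray(q)
        q_arb = np.where(q_mono < 1.0, (np.asarray(q) - q_mono) / (1.0 - q_mono), 0.0)
        arb = norm.cdf(z) < q_arb[None, :]
        masks[blk] = mono | arb
    return masks


def impose_missingness(bundle: TruthBundle, mcfg: MissingnessConfig) -> TruthBundle:
    """Mask cells of ``bundle.complete_labs`` under the configured mechanism.

    Returns a new bundle whose ``observed_labs`` carries the mask; the
    complete table is untouched.  Realized per-variable missingness is
    within a few tenths of a percentage point of target for the monotone
    part and within binomial noise for the arbitrary/MCAR part.
    """
    labs = bundle.complete_labs
    if labs.n_missing() > 0:
        raise ValueError("complete_labs must have no missing cells")
    analytes = labs.analytes
    mcfg.validate(len(analytes))
    rng = np.random.default_rng(mcfg.seed)

    pre_rates = np.atleast_1d(np.asarray(mcfg.target_rates, dtype=float))
    post_rates = pre_rates if mcfg.post_rates is None else np.atleast_1d(
        np.asarray(mcfg.post_rates, dtype=float))
    rates = {"pre": pre_rates, "post": post_rates}
    n = labs.n_patients

    if mcfg.mechanism == "MCAR":
        masks = {blk: rng.random((n, len(analytes))) < rates[blk][None, :]
                 for blk in BLOCKS}
    else:
        if mcfg.mechanism == "MNAR_monotone":
            score = bundle.burden.to_numpy()
        else:  # MAR: utilization driven by the *observed* comorbidity count
            counts = bundle.comorbidity.to_numpy().sum(axis=1).astype(float)
            sd = counts.std()
            score = (counts - counts.mean()) / (sd if sd > 0 else 1.0)
        u = mcfg.burden_missing_loading * score + rng.standard_normal(n)
        panel = (bundle.cohort_config.panel_index
                 if bundle.cohort_config is not None
                 else np.zeros(len(analytes), dtype=int))
        masks = _monotone_arbitrary_mask(rates, u, mcfg, panel, rng)

    observed = labs.data.copy()
    arr = observed.to_numpy()
    for blk in BLOCKS:
        cidx = observed.columns.get_indexer([(a, blk) for a in analytes])
        blk_arr = arr[:, cidx]
        blk_arr[masks[blk]] = np.nan
        arr[:, cidx] = blk_arr
    observed = pd.DataFrame(arr, index=observed.index, columns=observed.columns)

    return replace(
        bundle,
        observed_labs=labs.with_data(observed),
        missingness_config=mcfg,
    )


# ---------------------------------------------------------------------------
# presets


def _split_panels(p: int) -> list[tuple[str, int]]:
    n_panels = min(6, max(2, round(p / 4)))
    base, extra = divmod(p, n_panels)
    return [(_PANEL_NAMES[i], base + (1 if i < extra else 0)) for i in range(n_panels)]


def preset(name: str, n_patients: int | None = None,
           n_analytes: int | None = None, seed: int = 0
           ) -> tuple[CohortConfig, MissingnessConfig]:
    """Named study conditions emulating the two source cohorts.

    ``gnsis-like``: 45 analytes over 9037 patients; pre-block missingness
    spanning ~36-74% with clearly lower post-block missingness.
    ``hf-like``: 38 analytes over 5192 patients; both blocks ~58-75% with
    before approximately equal to after.

    ``n_patients`` / ``n_analytes`` shrink the cohort (the per-analyte rate
    range is preserved by re-spacing) for desk-scale runs.
    """
    if name == "gnsis-like":
        n = 9037 if n_patients is None else int(n_patients)
        p = 45 if n_analytes is None else int(n_analytes)
        pre = np.linspace(0.36, 0.74, p)
        post = np.clip(pre - 0.30, 0.02, None)
    elif name == "hf-like":
        n = 5192 if n_patients is None else int(n_patients)
        p = 38 if n_analytes is None else int(n_analytes)
        pre = np.linspace(0.58, 0.745, p)
        post = pre.copy()
    else:
        raise ValueError(f"unknown preset {name!r}; valid presets: {PRESETS}")

    ss = np.random.SeedSequence(seed)
    cohort_seed, missing_seed = (int(s) for s in ss.generate_state(2) % (2 ** 31))

    means = np.linspace(5.0, 240.0, p)
    sds = 0.15 * means + 0.5
    time_effect = -0.06 * sds

    cfg = CohortConfig(
        n_patients=n,
        panels=_split_panels(p),
        within_panel_corr=0.5,
        between_panel_corr=0.1,
        patient_intercept_sd=1.0,
        residual_sd=1.0,
        analyte_means=means,
        analyte_sds=sds,
        time_effect=time_effect,
        n_comorbidity_codes=30,
        burden_loading=1.0,
        burden_lab_loading=0.35,
        seed=cohort_seed,
    )
    mcfg = MissingnessConfig(
        mechanism="MNAR_monotone",
        target_rates=pre,
        post_rates=post,
        monotone_weight=0.8,
        burden_missing_loading=1.0,
        # near all-or-none panel ordering keeps a small minority (~4% at
        # full scale) of patients fully complete, as real cohorts show
        panel_corr=0.95,
        seed=missing_seed,
    )
    return cfg, mcfg


# ---------------------------------------------------------------------------
# long-format emission (exercises preprocessing extraction)


def to_long_records(bundle: TruthBundle, window_days: int = 1095,
                    max_repeats: int = 3,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit long-format records for the observed cells of a bundle.

    Each observed (patient, analyte, block) cell yields 1..max_repeats
    records inside the extraction window; the record closest to the index
    date (last before / first after) carries the cell's value so that
    :func:`labmi.preprocessing.extract_time_blocks` recovers the wide table
    exactly.  Decoy records carry perturbed values at farther offsets.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labs = bundle.observed_labs
    rows: list[tuple] = []
    for blk, sign in (("pre", -1), ("post", 1)):
        frame = labs.block(blk)
        for a in frame.columns:
            col = frame[a]
            obs = col.dropna()
            n_rep = rng.integers(1, max_repeats + 1, len(obs))
            # nearest offset first; decoys strictly farther out
            near = rng.integers(1, max(2, window_days // 3), len(obs))
            for (pid, val), reps, d0 in zip(obs.items(), n_rep, near):
                offsets = [int(d0)]
                while len(offsets) < reps:
                    d = int(offsets[-1] + rng.integers(1, window_days // 3))
                    if d > window_days:
                        break
                    offsets.append(d)
                for i, d in enumerate(offsets):
                    v = float(val) if i == 0 else float(val) + float(rng.standard_normal())
                    day = sign * d if not (blk == "pre" and d == 0) else 0
                    rows.append((pid, a, day, v))
    out = pd.DataFrame(rows, columns=["patient_id", "analyte_id",
                                      "days_from_index", "value"])
    return out.sort_values(["patient_id", "analyte_id", "days_from_index"],
                           kind="stable", ignore_index=True)
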