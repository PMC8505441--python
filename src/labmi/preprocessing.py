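"""From long-format lab records to the analysis-ready wide table.

The rules mirror common EHR lab-cleaning practice around a disease index
date: keep the last valid observation before and the first after the index
date, mask values outside k x IQR fences as invalid, drop analytes whose
pre-block missingness is at or above a threshold, log-transform skewed
analytes, and drop comorbidity codes observed in too few patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from labmi.tables import BLOCKS, LabTable, from_blocks

LONG_COLUMNS = ("patient_id", "analyte_id", "days_from_index", "value")


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing step.

    ``extracted``/``outlier_masked``/``retained`` are per-analyte observed
    cell counts and reconcile exactly: extracted = retained + outlier_masked.
    """

    extracted: dict = field(default_factory=dict)
    outlier_masked: dict = field(default_factory=dict)
    retained: dict = field(default_factory=dict)
    dropped_analytes: dict = field(default_factory=dict)
    dropped_codes: dict = field(default_factory=dict)


def extract_time_blocks(long_records: pd.DataFrame,
                        index_dates: pd.Series | None = None,
                        window_days: int = 1095) -> LabTable:
    """Extract the last-before / first-after value per (patient, analyte).

    ``long_records`` must carry signed day offsets from the index date
    (column ``days_from_index``; negative or zero = before).  The pre cell is
    the value at the maximum offset in [-window_days, 0] — a same-day draw
    counts as "before" — and the post cell the value at the minimum offset in
    (0, +window_days].  Records outside the window are ignored.  Duplicate
    records at the identical offset are averaged with a warning.

    ``index_dates`` (optional) fixes the patient universe: patients listed
    there appear as all-missing rows even without qualifying records.
    """
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    missing_cols = [c for c in LONG_COLUMNS if c not in long_records.columns]
    if missing_cols:
        raise ValueError(
            f"long records lack columns {missing_cols}; expected {list(LONG_COLUMNS)}"
        )
    rec = long_records.loc[:, list(LONG_COLUMNS)].copy()
    rec["days_from_index"] = pd.to_numeric(rec["days_from_index"])
    rec["value"] = pd.to_numeric(rec["value"])

    dup = rec.duplicated(subset=["patient_id", "analyte_id", "days_from_index"],
                         keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} records share an identical offset; "
            "ties resolved by averaging", stacklevel=2)
        rec = (rec.groupby(["patient_id", "analyte_id", "days_from_index"],
                           as_index=False, sort=False)["value"].mean())

    analytes = sorted(rec["analyte_id"].unique())
    if index_dates is not None:
        patients = pd.Index(index_dates.index, name="patient_id")
    else:
        patients = pd.Index(sorted(rec["patient_id"].unique()), name="patient_id")

    d = rec["days_from_index"]
    pre = rec[(d >= -window_days) & (d <= 0)]
    post = rec[(d > 0) & (d <= window_days)]

    def _pick(sub: pd.DataFrame, take_last: bool) -> pd.DataFrame:
        if sub.empty:
            return pd.DataFrame(np.nan, index=patients, columns=analytes)
        sub = sub.sort_values("days_from_index", kind="stable")
        chosen = sub.groupby(["patient_id", "analyte_id"], sort=False).nth(
            -1 if take_last else 0)
        wide = chosen.pivot_table(index="patient_id", columns="analyte_id",
                                  values="value", aggfunc="first")
        return wide.reindex(index=patients, columns=analytes)

    return from_blocks(_pick(pre, take_last=True), _pick(post, take_last=False))


def mask_outliers_iqr(table: LabTable, k: float = 3.0
                      ) -> tuple[LabTable, PreprocessReport]:
    """Mask cells outside [Q1 - k*IQR, Q3 + k*IQR] per analyte.

    Fences are computed on the pooled pre+post observed values of each
    analyte, with quartiles by linear interpolation between order
    statistics.  Analytes with fewer than 4 observed values are skipped with
    a warning.  ``k = inf`` disables masking entirely.
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    report = PreprocessReport()
    data = table.data.copy()
    for a in table.analytes:
        cols = [(a, b) for b in BLOCKS if (a, b) in data.columns]
        vals = data.loc[:, cols].to_numpy().ravel()
        obs = vals[~np.isnan(vals)]
        report.extracted[a] = int(obs.size)
        if np.isinf(k):
            report.outlier_masked[a] = 0
            report.retained[a] = int(obs.size)
            continue
        if obs.size < 4:
            warnings.warn(f"analyte {a!r} has <4 observed values; "
                          "outlier fences skipped", stacklevel=2)
            report.outlier_masked[a] = 0
            report.retained[a] = int(obs.size)
            continue
        q1, q3 = np.percentile(obs, [25, 75])  # linear interpolation
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        sub = data.loc[:, cols]
        bad = (sub < lo) | (sub > hi)
        n_bad = int(bad.to_numpy().sum())
        data.loc[:, cols] = sub.mask(bad)
        report.outlier_masked[a] = n_bad
        report.retained[a] = int(obs.size) - n_bad
    return table.with_data(data), report


def filter_variables_by_missingness(table: LabTable, threshold: float = 0.75
                                    ) -> tuple[LabTable, PreprocessReport]:
    """Drop analytes whose pre-block missingness fraction is >= threshold.

    The filter is evaluated on the pre block, which is the imputation target
    in all evaluations; the strict inequality keeps an analyte at exactly
    ``threshold - epsilon`` missingness.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    report = PreprocessReport()
    frac = table.missing_fraction("pre")
    drop = [a for a in table.analytes if frac[a] >= threshold]
    keep = [a for a in table.analytes if a not in drop]
    if not keep:
        raise ValueError("all analytes exceed the missingness threshold")
    report.dropped_analytes = {a: float(frac[a]) for a in drop}
    cols = [(a, b) for a in keep for b in BLOCKS if (a, b) in table.data.columns]
    return table.with_data(table.data.loc[:, cols]), report


def log_transform(table: LabTable, analytes: list) -> LabTable:
    """Natural-log transform the named analytes (both blocks).

    Any non-positive observed value is an error naming the analyte and the
    patient, since the transform would be undefined there.
    """
    if not analytes:
        return table.copy()
    unknown = [a for a in analytes if a not in table.analytes]
    if unknown:
        raise KeyError(f"unknown analytes {unknown}")
    data = table.data.copy()
    for a in analytes:
        cols = [(a, b) for b in BLOCKS if (a, b) in data.columns]
        sub = data.loc[:, cols]
        bad = sub <= 0
        if bad.to_numpy().any():
            pid = sub.index[bad.any(axis=1)][0]
            raise ValueError(
                f"analyte {a!r} has a non-positive value for patient {pid!r}; "
                "cannot log-transform")
        data.loc[:, cols] = np.log(sub)
    return LabTable(data, table.log_transformed | frozenset(analytes))


def filter_comorbidity_codes(comorbidity: pd.DataFrame,
                             min_prevalence: float = 0.20
                             ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop comorbidity codes observed in fewer than ``min_prevalence`` of
    patients ("at least" semantics: a code at exactly the threshold stays).
    """
    vals = comorbidity.to_numpy()
    if not np.isin(vals[~pd.isna(vals)], (0, 1)).all():
        raise ValueError("comorbidity table must be binary (0/1)")
    report = PreprocessReport()
    prev = comorbidity.mean(axis=0)
    keep = prev.index[prev >= min_prevalence]
    if len(keep) == 0:
        raise ValueError("no comorbidity codes reach the prevalence threshold")
    report.dropped_codes = {c: float(prev[c]) for c in comorbidity.columns
                            if c not in set(keep)}
    return comorbidity.loc[:, keep], report
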