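"""Generate the reduced-scale study cohort used by the downstream analyses.

A gnsis-like synthetic cohort (2000 patients, 12 analytes) is drawn,
informative monotone missingness is imposed, and the observed/truth tables,
comorbidity matrix, and long-format records are written under
results/data/.  Prints the realized missingness range, the complete-case
count, and the panel structure.
"""

from pathlib import Path

import numpy as np

from labmi import io as lio
from labmi.evaluation import complete_cases
from labmi.synthetic import (generate_complete_cohort, impose_missingness,
                             preset, to_long_records)

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg, mcfg = preset("gnsis-like", n_patients=2000, n_analytes=12,
                       seed=SEED)
    bundle = impose_missingness(generate_complete_cohort(cfg), mcfg)
    table = bundle.observed_labs

    lio.write_lab_wide(table, OUT / "labs_wide.csv")
    lio.write_lab_wide(bundle.complete_labs, OUT / "labs_truth_wide.csv")
    lio.write_lab_long(to_long_records(bundle, rng=np.random.default_rng(SEED)),
                       OUT / "labs_long.csv")
    lio.write_comorbidity(bundle.comorbidity, OUT / "comorbidity.csv")
    lio.write_manifest(OUT / "manifest.json", command="01_synthesize_cohort",
                       seed=SEED, cohort_config=cfg, missingness_config=mcfg)

    pre_miss = table.missing_fraction("pre")
    post_miss = table.missing_fraction("post")
    cc = len(complete_cases(table))
    print(f"cohort: {table.n_patients} patients, {len(table.analytes)} "
          f"analytes in {len(cfg.panels)} panels")
    print(f"pre-block missingness:  {pre_miss.min():.1%} .. {pre_miss.max():.1%}")
    print(f"post-block missingness: {post_miss.min():.1%} .. {post_miss.max():.1%}")
    print(f"complete cases (pre block): {cc} ({cc / table.n_patients:.1%})")
    print(f"wrote cohort files to {OUT}")


if __name__ == "__main__":
    main()
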