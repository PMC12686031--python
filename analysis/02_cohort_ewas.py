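"""Per-cohort EWAS for both adipokines under all four covariate models,
followed by probe filtering and bias/inflation correction.

Writes the corrected association tables and a per-cohort/model report of
the estimated bias and inflation (expected ~0.00 and ~1.00: the per-CpG
t-tests are well calibrated and only 1% of CpGs carry signal).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, consortium

from adipomethyl import ewas, inflation, io


def main():
    ann = io.read_probe_annotation(RESULTS / "annotation.tsv")
    report = []
    for adipokine in ("adiponectin", "leptin"):
        datasets, _ = consortium(adipokine)
        for tag in ewas.MODEL_TAGS:
            spec = ewas.ModelSpec(phenotype=adipokine, model_tag=tag)
            adjusted = []
            for ds in datasets:
                rec = ewas.run_model(ds, spec)
                rec, filt = ewas.filter_probes(rec, ann)
                fit = inflation.fit_mixture(
                    inflation.zstat(rec["beta"], rec["se"]))
                adjusted.append(inflation.adjust_statistics(rec, fit))
                report.append({"adipokine": adipokine, "cohort": ds.cohort_id,
                               "model": tag, "bias": round(fit.bias, 4),
                               "inflation": round(fit.inflation, 4),
                               "probes_kept": filt.kept})
            out = pd.concat(adjusted, ignore_index=True)
            io.write_table(out, RESULTS / f"ewas_{adipokine}_{tag}.tsv")
    rep = pd.DataFrame(report)
    io.write_table(rep, RESULTS / "bias_inflation_report.tsv")
    print(rep.groupby(["adipokine", "model"])[["bias", "inflation"]]
          .mean().round(3))
    print(f"\nbias within ±{rep['bias'].abs().max():.3f}, "
          f"inflation within {rep['inflation'].min():.3f}–"
          f"{rep['inflation'].max():.3f} across all cohort/model fits")


if __name__ == "__main__":
    main()
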