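"""Generate the synthetic five-cohort consortium and its annotation.

Writes the planted ground truth, probe annotation, gene models, trait
catalogue and chromatin-state segmentation under results/analysis/.
Cohort-level matrices are regenerated on demand from the seed by the
later drivers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, annotation, consortium

from adipomethyl import io


def main():
    for adipokine in ("adiponectin", "leptin"):
        datasets, truth = consortium(adipokine)
        io.write_table(truth.effects, RESULTS / f"truth_{adipokine}.tsv")
        total = sum(len(d.beta) for d in datasets)
        clip = max(d.clip_fraction for d in datasets)
        planted = int((truth.effects["true_beta"] != 0).sum())
        print(f"{adipokine}: {len(datasets)} cohorts, n={total}, "
              f"{planted} planted CpGs, max clip fraction {clip:.3%}")

    ann, genes, catalogue, state_bed = annotation()
    io.write_probe_annotation(ann, RESULTS / "annotation.tsv")
    io.write_gene_models(genes, RESULTS / "gene_models.tsv")
    io.write_table(catalogue, RESULTS / "trait_catalogue.tsv")
    io.write_state_bed(state_bed, RESULTS / "states_E062.bed")
    flagged = int((ann[["on_sex_chrom", "blacklisted",
                        "variant_or_ambiguous"]].any(axis=1)).sum())
    print(f"annotation: {len(ann)} probes ({flagged} carry exclusion flags), "
          f"{len(genes)} genes, {len(catalogue)} catalogue traits")


if __name__ == "__main__":
    main()
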