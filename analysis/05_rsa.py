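#!/usr/bin/env python
"""Representational similarity analysis of networks against task activity.

For each study, per-subject activation RDMs (1 - Pearson across the three
task contrasts, per ROI pair) are correlated (Spearman, upper triangle,
903 pairs) with the model RDM of each detected partition (0 within a
module, 1 between). Group inference: one-sample t-test over Fisher-
transformed subject correlations, Bonferroni-corrected across the 2 models
x 3 studies. The two model RDMs are also compared to each other with both
a parametric and a Mantel permutation p-value.

Writes results/05_rsa.json.
"""

import argparse
import json
from pathlib import Path

from netsig import demo_design
from netsig.graph import Partition
from netsig.rsa import activation_rdms, compare_model_rdms, group_rsa, model_rdm
from netsig.simulate import generate_task_betas

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-perm", type=int, default=10_000)
    args = ap.parse_args()

    design = demo_design(seed=args.seed)
    partitions = json.loads((RESULTS / "03_partitions.json").read_text())
    models = {
        branch: model_rdm(Partition(assignment=payload["assignment"],
                                    q=payload["q"], roi_set=design.roi_set))
        for branch, payload in partitions.items()
    }
    studies = generate_task_betas(design, n_studies=3)

    out = {"group_rsa": {}, "model_comparison": {}}
    n_comparisons = len(models) * len(studies)
    for branch, model in models.items():
        out["group_rsa"][branch] = {}
        for betas in studies:
            res = group_rsa(activation_rdms(betas), model,
                            n_comparisons=n_comparisons)
            out["group_rsa"][branch][betas.study_id] = {
                "mean_rho": res.mean_rho, "t": res.t,
                "p_uncorrected": res.p_uncorrected,
                "p_corrected": res.p_corrected,
            }
            print(f"{branch} model x {betas.study_id}: mean rho = "
                  f"{res.mean_rho:.3f}, p_corrected = {res.p_corrected:.2g}")

    mc = compare_model_rdms(models["structural"], models["functional"],
                            n_perm=args.n_perm, seed=args.seed)
    out["model_comparison"] = {
        "rho": mc.rho, "p_parametric": mc.p_parametric,
        "p_permutation": mc.p_permutation, "n_pairs": mc.n_pairs,
    }
    print(f"model-to-model: rho = {mc.rho:.3f} over {mc.n_pairs} pairs "
          f"(parametric p = {mc.p_parametric:.2g}, "
          f"permutation p = {mc.p_permutation:.2g})")

    path = RESULTS / "05_rsa.json"
    path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
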