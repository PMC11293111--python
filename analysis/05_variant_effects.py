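"""Variant-effect evaluation: single-task |SAD| separation of causal vs
neutral variants, the cross-validated random-forest classifier, allelic
imbalance sign accuracy, and direction-of-effect AUC.
"""

import json

from _common import RESULTS, load_state, parse_args
import numpy as np

from ctsbench import study


def main():
    args = parse_args()
    state = load_state(args.seed, "data", "zoo")
    var = study.variant_eval(state["data"], state["zoo"], seed=args.seed + 17)
    var["imbalance_model"].to_csv(RESULTS / "allelic_imbalance.tsv", sep="\t",
                                  index=False)
    var["direction_of_effect"].to_csv(RESULTS / "direction_of_effect.tsv",
                                      sep="\t", index=False)
    summary = {
        "n_variants": var["n_variants"],
        "sad_mwu_p": var["sad_mwu_p"],
        "classifier_auprc_truth": var["classifier_truth"]["auprc_mean"],
        "classifier_auprc_model": var["classifier_model"]["auprc_mean"],
        "classifier_auprc_shuffled": var["classifier_shuffled"]["auprc_mean"],
        "oracle_sign_accuracy":
            float(var["imbalance_oracle"].iloc[0]["accuracy"]),
        "model_sign_accuracy":
            float(var["imbalance_model"].iloc[0]["accuracy"]),
    }
    (RESULTS / "variant_effects.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
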