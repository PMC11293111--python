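"""Stratified reference accuracy: Pearson R in ubiquitous vs cell
type-specific test peaks per model and replicate, cross-cell-type
over-correlation of predictions, and replicate CV with the one-sided
Mann-Whitney test.
"""

from _common import RESULTS, load_state, parse_args, save_state

from ctsbench import study


def main():
    args = parse_args()
    state = load_state(args.seed, "data", "zoo")
    ref = study.reference_eval(state["data"], state["zoo"])
    ref["pearson"].to_csv(RESULTS / "stratified_pearson.tsv", sep="\t",
                          index=False)
    ref["cross_celltype"].to_csv(RESULTS / "cross_celltype_correlation.tsv",
                                 sep="\t", index=False)
    ref["replicate_cv"].to_csv(RESULTS / "replicate_cv.tsv", sep="\t",
                               index=False)
    p = ref["pearson"]
    for model in ("multi_m1", "single"):
        ub = study.mean_r(p, model, "ubiquitous")
        sp = study.mean_r(p, model, "specific")
        print(f"{model:9s}  R(ubiquitous) {ub:5.3f}   R(specific) {sp:6.3f}")
    cc = ref["cross_celltype"].groupby("model")["mean_pairwise_r"].mean()
    print("cross-cell-type R of predictions in specific peaks:")
    print(cc.round(3).to_string())
    state["ref"] = ref
    save_state(args.seed, state)


if __name__ == "__main__":
    main()
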