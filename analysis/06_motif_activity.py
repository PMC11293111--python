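"""Motif-insertion TF activity: single-task activity scores for every PWM
(grammar motifs plus distractors) over dinucleotide-shuffled backgrounds,
and recovery of each cell type's planted specific motifs.
"""

from _common import RESULTS, load_state, parse_args

from ctsbench import study


def main():
    args = parse_args()
    state = load_state(args.seed, "data", "zoo")
    data = state["data"]
    motif = study.motif_eval(data, state["zoo"], seed=args.seed + 23)
    motif["activity"].round(4).to_csv(RESULTS / "motif_activity.tsv", sep="\t")
    shared = set(data.grammar.shared_motifs)
    print(f"activity over {motif['n_backgrounds']} shuffled backgrounds")
    for ct in data.cell_types:
        row = motif["activity"].loc[ct].drop(labels=list(shared))
        own = data.grammar.specific_motifs[ct]
        mark = "OK " if row.idxmax() in own else "MISS"
        print(f"  {ct}: top restricted motif {row.idxmax()} "
              f"(own specific: {own})  [{mark}]")


if __name__ == "__main__":
    main()
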