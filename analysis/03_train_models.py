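"""Train the model zoo: narrow baseline multi-task CNN and one single-task
CNN per cell type, three seed replicates each, Poisson loss, chromosome
splits (validation chr7, test chr4+chr5).
"""

import pandas as pd
from _common import RESULTS, load_state, parse_args, save_state

from ctsbench import study


def main():
    args = parse_args()
    state = load_state(args.seed, "data")
    zoo = study.train_zoo(state["data"], capacities=(1,), single_task=True,
                          seed=args.seed)
    rows = []
    for name, ens in zoo.items():
        ensembles = ens.items() if isinstance(ens, dict) else [(name, ens)]
        for tag, e in ensembles:
            for r, hist in enumerate(e.histories):
                rows.append({"model": name if name != "single" else f"single:{tag}",
                             "replicate": r,
                             "stopped_epoch": hist["stopped_epoch"],
                             "best_val_loss": hist["best_val_loss"]})
    pd.DataFrame(rows).to_csv(RESULTS / "training_summary.tsv", sep="\t",
                              index=False)
    state["zoo"] = zoo
    save_state(args.seed, state)
    print(f"trained {len(rows)} models; summary in results/training_summary.tsv")


if __name__ == "__main__":
    main()
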