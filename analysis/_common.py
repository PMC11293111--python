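import argparse
import pickle
import sys
from pathlib import Path

import numpy as np
import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def parse_args():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    return ap.parse_args()


def study_path(seed):
    SCRATCH.mkdir(exist_ok=True)
    return SCRATCH / f"study_state_seed{seed}.pkl"


def load_state(seed, *keys):
    path = study_path(seed)
    if not path.exists():
        sys.exit(f"run the earlier analysis steps first ({path} missing)")
    with open(path, "rb") as fh:
        state = pickle.load(fh)
    missing = [k for k in keys if k not in state]
    if missing:
        sys.exit(f"state at {path} lacks {missing}; run the earlier steps")
    return state


def save_state(seed, state):
    with open(study_path(seed), "wb") as fh:
        pickle.dump(state, fh)
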