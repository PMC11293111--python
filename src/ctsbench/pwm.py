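"""Position weight matrices: container, JASPAR pfm I/O, scanning and sampling.

A PWM here is a per-position probability distribution over the four bases
(rows in A, C, G, T order). Log-odds scores are computed against a background
base distribution (uniform 0.25 by default) with a small pseudocount so that
zero-probability entries stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class PWM:
    """A named position probability matrix of shape (4, width)."""

    name: str
    matrix: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"PWM {self.name!r}: matrix must be 4 x width")
        if self.width < 4:
            raise ValueError(f"PWM {self.name!r}: width must be >= 4, got {self.width}")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1 (got {colsums})")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """Log-odds matrix vs. a background base distribution (default uniform)."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = (self.matrix + self.pseudocount) / (1.0 + 4 * self.pseudocount)
        return np.log(p) - np.log(bg)[:, None]

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[COMPLEMENT_INDEX, ::-1], self.pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def sample(self, rng: np.random.Generator) -> str:
        """Sample one motif realization, column-wise."""
        idx = [rng.choice(4, p=self.matrix[:, j] / self.matrix[:, j].sum())
               for j in range(self.width)]
        return "".join(BASES[i] for i in idx)

    def score_sequence(self, seq: str, background: np.ndarray | None = None) -> float:
        """Log-odds score of a sequence of exactly this width."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != PWM width {self.width}")
        lo = self.log_odds(background)
        return float(sum(lo[BASE_INDEX[b], j] for j, b in enumerate(seq)))

    def expected_score(self, background: np.ndarray | None = None) -> float:
        """Expected log-odds score of a realization sampled from the PWM itself."""
        lo = self.log_odds(background)
        return float((self.matrix * lo).sum())


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode ACGT (N and anything else -> -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_sequence(pwm: PWM, seq: str, background: np.ndarray | None = None,
                  both_strands: bool = True) -> np.ndarray:
    """Log-odds score at every offset; returns max over strands per offset.

    Positions containing non-ACGT characters score -inf.
    """
    enc = encode_sequence(seq)
    n = len(enc) - pwm.width + 1
    if n <= 0:
        return np.empty(0)
    lo = pwm.log_odds(background)
    scores = _scan_encoded(lo, enc)
    if both_strands:
        lo_rc = pwm.reverse_complement().log_odds(background)
        scores = np.maximum(scores, _scan_encoded(lo_rc, enc))
    return scores


def _scan_encoded(log_odds: np.ndarray, enc: np.ndarray) -> np.ndarray:
    w = log_odds.shape[1]
    n = len(enc) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds[safe, np.arange(w)].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def best_hit(pwm: PWM, seq: str, background: np.ndarray | None = None) -> tuple[int, float]:
    """(offset, score) of the best match on either strand."""
    scores = scan_sequence(pwm, seq, background)
    if scores.size == 0:
        raise ValueError("sequence shorter than PWM width")
    i = int(scores.argmax())
    return i, float(scores[i])


def random_pwm(name: str, width: int, rng: np.random.Generator,
               min_dominant: float = 0.75, max_dominant: float = 0.95) -> PWM:
    """Generate a synthetic well-peaked PWM (used for planted regulatory grammar)."""
    mat = np.empty((4, width))
    for j in range(width):
        dom = rng.integers(4)
        p_dom = rng.uniform(min_dominant, max_dominant)
        rest = rng.dirichlet(np.ones(3)) * (1.0 - p_dom)
        col = np.insert(rest, dom, p_dom)
        mat[:, j] = col
    return PWM(name, mat)


def scrambled_pwm(pwm: PWM, rng: np.random.Generator, name: str | None = None) -> PWM:
    """Column-permuted, base-permuted copy: width-matched distractor motif."""
    perm_cols = rng.permutation(pwm.width)
    mat = pwm.matrix[:, perm_cols]
    mat = mat[rng.permutation(4), :]
    return PWM(name or f"{pwm.name}_scrambled", mat, pwm.pseudocount)


# ---------------------------------------------------------------------------
# JASPAR pfm text I/O
# ---------------------------------------------------------------------------

def write_jaspar(pwms: list[PWM], path, counts_scale: float = 100.0) -> None:
    """Write PWMs in JASPAR 2016+ pfm format (counts = probabilities * scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v * counts_scale:.4f}" for v in pwm.matrix[i])
                fh.write(f"{base}  [ {row} ]\n")


def read_jaspar(path) -> list[PWM]:
    """Read JASPAR pfm text; counts are normalized column-wise to probabilities."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(_finish_jaspar(name, rows, lineno))
                name = line[1:].split()[0]
                rows = []
            else:
                body = line
                if body[0] in BASES and "[" in body:
                    body = body.split("[", 1)[1].rsplit("]", 1)[0]
                try:
                    rows.append([float(tok) for tok in body.split()])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-numeric count") from exc
    if name is not None:
        pwms.append(_finish_jaspar(name, rows, lineno))
    return pwms


def _finish_jaspar(name: str, rows: list[list[float]], lineno: int) -> PWM:
    if len(rows) != 4:
        raise ValueError(f"motif {name!r} ending near line {lineno}: expected 4 base rows")
    mat = np.asarray(rows, dtype=float)
    colsums = mat.sum(axis=0)
    if (colsums <= 0).any():
        raise ValueError(f"motif {name!r}: column with non-positive total count")
    return PWM(name, mat / colsums)
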