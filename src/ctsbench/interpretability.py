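"""Model interpretability: motif-insertion TF activity, ISM, gradient*input,
and a cross-cell-type motif-match Jaccard comparison.

The TF activity score for a motif is the mean (over dinucleotide-shuffled
background sequences) difference in predicted accessibility between the
background with a sampled motif realization inserted at its centre and the
background itself. Attribution maps come from in silico mutagenesis (one
forward pass per substitution) or gradient*input; simple seqlet calling plus
PWM correlation matching yields per-cell-type motif sets whose pairwise
Jaccard similarity summarizes how distinct the learned grammars are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models as M
from . import nn
from .pwm import PWM


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Euler-path construction)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle preserving all 16 dinucleotide counts and the first/last base.

    Altschul-Erickson construction: pick a "last edge" per vertex forming a
    tree into the final base's vertex, shuffle the remaining edges, then walk
    the Euler path.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence must contain only A, C, G, T")
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last_vertex = seq[-1]

    for _ in range(10000):
        last_edge: dict[str, str] = {}
        for u in vertices:
            if u == last_vertex:
                continue
            last_edge[u] = edges[u][rng.integers(len(edges[u]))]
        if _reaches(last_edge, vertices, last_vertex):
            break
    else:  # pragma: no cover - 4-vertex graphs converge almost immediately
        raise RuntimeError("failed to sample a connected last-edge tree")

    out_lists: dict[str, list[str]] = {}
    for u in vertices:
        pool = list(edges[u])
        if u in last_edge:
            pool.remove(last_edge[u])
        rng.shuffle(pool)
        if u in last_edge:
            pool.append(last_edge[u])
        out_lists[u] = pool

    walk = [seq[0]]
    pos = {u: 0 for u in vertices}
    u = seq[0]
    for _ in range(len(seq) - 1):
        v = out_lists[u][pos[u]]
        pos[u] += 1
        walk.append(v)
        u = v
    return "".join(walk)


def _reaches(last_edge: dict[str, str], vertices: list[str], sink: str) -> bool:
    for u in vertices:
        seen = set()
        while u != sink:
            if u in seen or u not in last_edge:
                return False
            seen.add(u)
            u = last_edge[u]
    return True


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


def make_backgrounds(peak_seqs: list[str], n: int = 1000, seed: int = 0) -> list[str]:
    """n dinucleotide-shuffled background sequences drawn from peak sequences."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        src = peak_seqs[rng.integers(len(peak_seqs))]
        out.append(dinucleotide_shuffle(src, int(rng.integers(2 ** 31))))
    return out


# ---------------------------------------------------------------------------
# Motif-insertion activity
# ---------------------------------------------------------------------------

@dataclass
class ActivityScore:
    pwm_name: str
    scores: dict[str, float]      # task -> mean (inserted - background) prediction
    n_backgrounds: int
    seed: int


def motif_activity(predict_fn, pwm: PWM, backgrounds: list[str], tasks: list[str],
                   seed: int = 0) -> ActivityScore:
    """Mean per-task prediction difference from centre-inserting one sampled
    motif realization into each background sequence."""
    if not backgrounds:
        raise ValueError("need at least one background sequence")
    L = len(backgrounds[0])
    if pwm.width > L:
        raise ValueError(f"motif width {pwm.width} exceeds background length {L}")
    rng = np.random.default_rng(seed)
    off = (L - pwm.width) // 2
    inserted = []
    for bg in backgrounds:
        real = pwm.sample(rng)
        inserted.append(bg[:off] + real + bg[off + pwm.width:])
    pred_bg = np.asarray(predict_fn(M.one_hot_batch(backgrounds)))
    pred_in = np.asarray(predict_fn(M.one_hot_batch(inserted)))
    diff = (pred_in - pred_bg).mean(axis=0)
    scores = {t: float(v) for t, v in zip(tasks, np.atleast_1d(diff))}
    return ActivityScore(pwm.name, scores, len(backgrounds), seed)


def activity_matrix(predict_fns: dict[str, object], pwms: list[PWM],
                    backgrounds: list[str], seed: int = 0):
    """cell type x motif activity matrix (each cell type scored by its own
    predictor on its own task)."""
    import pandas as pd
    rows = {}
    for ct, fn in predict_fns.items():
        scores = {}
        for pwm in pwms:
            act = motif_activity(fn, pwm, backgrounds, tasks=[ct], seed=seed)
            scores[pwm.name] = act.scores[ct]
        rows[ct] = scores
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Attribution maps
# ---------------------------------------------------------------------------

@dataclass
class AttributionMap:
    method: str                   # 'ism' or 'grad_input'
    matrix: np.ndarray            # 4 x L (ISM: reference entries are 0)
    position_scores: np.ndarray   # L
    task: str = ""
    model_id: str = ""


def ism(model: nn.Sequential, seq: str, task: int = 0,
        batch_size: int = 256) -> AttributionMap:
    """In silico mutagenesis: prediction change for every substitution."""
    L = len(seq)
    X0 = M.one_hot(seq)[None]
    base = float(M.predict_model(model, X0)[0, task])
    muts, coords = [], []
    for i in range(L):
        for b in range(4):
            if X0[0, b, i] == 1.0:
                continue
            Xm = X0.copy()
            Xm[0, :, i] = 0.0
            Xm[0, b, i] = 1.0
            muts.append(Xm[0])
            coords.append((b, i))
    mat = np.zeros((4, L))
    if muts:
        preds = M.predict_model(model, np.stack(muts), batch_size=batch_size)[:, task]
        for (b, i), p in zip(coords, preds):
            mat[b, i] = p - base
    return AttributionMap("ism", mat, np.abs(mat).max(axis=0), task=str(task))


def grad_input(model: nn.Sequential, seq: str, task: int = 0) -> AttributionMap:
    """gradient*input attribution: d pred_task / dx summed against the one-hot."""
    X = M.one_hot(seq)[None]
    first = model.layers[0]
    had = getattr(first, "need_input_grad", None)
    if had is not None:
        first.need_input_grad = True
    try:
        out = model.forward(X)
        g = np.zeros_like(out)
        g[0, task] = 1.0
        dX = model.backward(g)[0]
    finally:
        if had is not None:
            first.need_input_grad = had
    gx = dX * X[0]
    return AttributionMap("grad_input", gx, gx.sum(axis=0), task=str(task))


# ---------------------------------------------------------------------------
# Seqlets & motif-match Jaccard across cell types
# ---------------------------------------------------------------------------

def jaccard_from_sets(a: set, b: set) -> float:
    """|A n B| / |A u B|; two empty sets -> 1, exactly one empty -> 0."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def find_seqlets(amap: AttributionMap, n_shuffles: int = 100, percentile: float = 95.0,
                 min_length: int = 3, seed: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of positions scoring above the given percentile of a
    position-shuffled null of the map's own position scores."""
    rng = np.random.default_rng(seed)
    scores = amap.position_scores
    null = np.concatenate([rng.permutation(scores) for _ in range(n_shuffles)])
    thr = np.percentile(null, percentile)
    mask = scores > thr
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_length:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_length:
        runs.append((start, len(mask)))
    return runs


def _best_profile_correlation(profile: np.ndarray, pwm: PWM) -> float:
    """Max Pearson correlation of the PWM log-odds against any width-aligned
    window of the attribution profile, both strands."""
    best = -1.0
    for cand in (pwm, pwm.reverse_complement()):
        lo = cand.log_odds()
        w = lo.shape[1]
        if profile.shape[1] < w:
            continue
        flat_lo = lo.ravel()
        for off in range(profile.shape[1] - w + 1):
            window = profile[:, off:off + w].ravel()
            if window.std() == 0 or flat_lo.std() == 0:
                continue
            r = float(np.corrcoef(window, flat_lo)[0, 1])
            best = max(best, r)
    return best


def match_seqlets_to_pwms(amap: AttributionMap, seqlets: list[tuple[int, int]],
                          pwms: list[PWM], n_null: int = 100, seed: int = 0):
    """(seqlet, pwm) correlation matches with permutation p-values.

    For each seqlet the window is extended to at least the PWM width; the
    null correlation distribution comes from column-permuted copies of the
    seqlet profile.
    """
    rng = np.random.default_rng(seed)
    L = amap.matrix.shape[1]
    rows = []
    for (s0, s1) in seqlets:
        for pwm in pwms:
            w = max(pwm.width, s1 - s0)
            centre = (s0 + s1) // 2
            a = max(0, min(centre - w // 2 - 2, L - w - 4))
            b = min(L, a + w + 4)
            profile = amap.matrix[:, a:b]
            obs = _best_profile_correlation(profile, pwm)
            null = []
            for _ in range(n_null):
                perm = profile[:, rng.permutation(profile.shape[1])]
                null.append(_best_profile_correlation(perm, pwm))
            p = (1 + sum(x >= obs for x in null)) / (1 + n_null)
            rows.append({"seqlet_start": s0, "seqlet_end": s1, "motif": pwm.name,
                         "correlation": obs, "p": p})
    import pandas as pd
    return pd.DataFrame(rows)


def seqlet_motif_jaccard(maps_per_celltype: dict[str, list[AttributionMap]],
                         pwms: list[PWM], q_threshold: float = 0.05,
                         n_null: int = 100, seed: int = 0):
    """Pairwise Jaccard of motif sets discovered from attribution maps.

    Per cell type: call seqlets on each map, match them to PWMs, BH-correct
    the permutation p-values across all matches, and keep motifs with any
    match at q < q_threshold. Returns (jaccard DataFrame, motif sets).
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    if len(maps_per_celltype) < 2:
        raise ValueError("need at least two cell types")
    motif_sets: dict[str, set] = {}
    for ct, maps in maps_per_celltype.items():
        tables = []
        for i, amap in enumerate(maps):
            seqlets = find_seqlets(amap, seed=seed + i)
            if seqlets:
                tables.append(match_seqlets_to_pwms(amap, seqlets, pwms,
                                                    n_null=n_null, seed=seed + i))
        if tables:
            table = pd.concat(tables, ignore_index=True)
            _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
            table["q"] = q
            # a positive correlation requirement avoids anti-matches
            hits = table[(table["q"] < q_threshold) & (table["correlation"] > 0)]
            motif_sets[ct] = set(hits["motif"])
        else:
            motif_sets[ct] = set()
    cts = list(maps_per_celltype)
    rows = []
    for i in range(len(cts)):
        for j in range(i + 1, len(cts)):
            rows.append({"cell_type_a": cts[i], "cell_type_b": cts[j],
                         "jaccard": jaccard_from_sets(motif_sets[cts[i]],
                                                      motif_sets[cts[j]])})
    return pd.DataFrame(rows), motif_sets
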