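"""Column-pair covariation scores, the phylogenetic null, and p-values.

Covariation is scored per column pair with a G-test on the joint residue
counts, optionally background-corrected with the average product correction
(APC). The null hypothesis — covariation due to shared phylogeny alone, not
to structure — is realised by re-evolving every column independently down
the working tree with exactly its Fitch substitution count worth of change
events; pooled scores from such null alignments give empirical p-values
with an exponential tail fit for extrapolation.

Covariation *power* — the probability that a pair with a given number of
observed substitutions would be detected as significantly covarying — is
self-calibrated against the structured-alignment simulator and used as the
weighted-Fisher weight source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from helixcov.msa_io import Alignment
from helixcov.phylo import PhyloTree, fitch_counts, _leaf_order_for

_RESIDUES = "ACGU"

#: absolute floor for any reported p-value (guards log-space aggregation)
P_FLOOR = 1e-300


def _joint_counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encoding and all-pairs joint counts.

    Returns ``(onehot, joint)`` with ``onehot`` of shape (n, L, 4) and
    ``joint[i, j, a, b]`` the number of sequences with residue a at column i
    and residue b at column j (missing data drops out automatically).
    """
    mat = aln.to_matrix()
    onehot = (mat[..., None] == np.arange(4, dtype=np.uint8)).astype(np.float64)
    joint = np.einsum("nia,njb->ijab", onehot, onehot, optimize=True)
    return onehot, joint


def _g_from_joint(joint: np.ndarray) -> np.ndarray:
    """G statistics for every column pair from the joint count tensor."""
    n_used = joint.sum(axis=(2, 3))
    row = joint.sum(axis=3)  # (L, L, 4) marginal at first column
    col = joint.sum(axis=2)  # (L, L, 4) marginal at second column
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, :, :, None] * col[:, :, None, :] / n_used[:, :, None, None]
        term = special.xlogy(joint, joint) - special.xlogy(joint, expected)
    g = 2.0 * np.nansum(term, axis=(2, 3))
    g = np.maximum(g, 0.0)  # clip tiny negative round-off
    g[n_used < 2] = np.nan
    np.fill_diagonal(g, np.nan)
    return g


def pair_score_gtest(aln: Alignment, i: int, j: int) -> float:
    """G-test covariation score for 1-based columns i and j.

    ``G = 2 sum_xy O_xy ln(O_xy / E_xy)`` over the 4x4 joint residue counts,
    with expectations from the marginal products; sequences with a gap or N
    at either column are excluded pairwise. Returns NaN when fewer than two
    usable sequences remain.
    """
    if i == j:
        raise ValueError("i and j must differ")
    if not (1 <= i <= aln.length and 1 <= j <= aln.length):
        raise IndexError(f"columns ({i}, {j}) out of range 1..{aln.length}")
    mat = aln.to_matrix()
    x, y = mat[:, i - 1], mat[:, j - 1]
    ok = (x != 4) & (y != 4)
    if ok.sum() < 2:
        return float("nan")
    counts = np.zeros((4, 4), dtype=float)
    np.add.at(counts, (x[ok].astype(int), y[ok].astype(int)), 1.0)
    n = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / n
        term = special.xlogy(counts, counts) - special.xlogy(counts, expected)
    return float(max(2.0 * np.nansum(term), 0.0))


def apc_correct(scores: np.ndarray) -> np.ndarray:
    """Average product correction: ``G'_ij = G_ij - mean_i * mean_j / grand``.

    Row means and the grand mean are taken over defined off-diagonal entries.
    A zero grand mean (all-zero matrix) leaves the scores unchanged.
    """
    out = scores.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_mean = np.nanmean(scores, axis=1)
        grand = np.nanmean(scores)
    if not np.isfinite(grand) or grand == 0.0:
        return out
    correction = np.outer(row_mean, row_mean) / grand
    return out - correction


def score_all_pairs(aln: Alignment, apc: bool = True) -> np.ndarray:
    """All-pairs G score matrix (symmetric, NaN diagonal), optionally APC-corrected."""
    _, joint = _joint_counts(aln)
    g = _g_from_joint(joint)
    if apc:
        g = apc_correct(g)
    return g


# ---------------------------------------------------------------------------
# phylogeny-preserving null


def _global_composition(aln: Alignment) -> np.ndarray:
    """Alignment-wide residue frequencies, broadcast to every column (L, 4).

    The null deliberately uses one shared stationary composition rather than
    each column's own: conditioning every null column on its observed
    composition shrinks the across-column score dispersion and detectably
    miscalibrates the pooled empirical p-values, while the alignment-wide
    composition keeps them uniform under the null. Column-to-column
    variation is still honoured through the Fitch-matched event counts.
    """
    mat = aln.to_matrix()
    counts = (mat[..., None] == np.arange(4, dtype=np.uint8)).sum(axis=(0, 1)).astype(float)
    if counts.sum() == 0:
        counts[:] = 1.0
    comp = counts / counts.sum()
    return np.broadcast_to(comp, (aln.length, 4)).copy()


def _place_events(
    rng: np.random.Generator, tree: PhyloTree, subs: np.ndarray
) -> np.ndarray:
    """Distribute each column's substitution events over branches.

    Column c receives exactly ``subs[c]`` substitution events, placed on
    branches with probability proportional to branch length (multinomially,
    so one branch can carry several). Returns an (n_nodes, L) count matrix.
    Matching the event *count* — not just its expectation — matters: the
    observed column's Fitch count is a fixed quantity, and a Poisson-
    dispersed null would contain far more invariant columns than the data.
    """
    n_nodes = tree.n_nodes
    L = subs.size
    events = np.zeros((n_nodes, L), dtype=np.int64)
    lengths = np.where(tree.parent >= 0, tree.branch_lengths, 0.0)
    total = lengths.sum()
    if total <= 0:
        # star/zero-length tree: spread events uniformly over non-root nodes
        lengths = (tree.parent >= 0).astype(float)
        total = lengths.sum()
    probs = lengths / total
    for c in np.flatnonzero(subs > 0):
        events[:, c] = rng.multinomial(int(subs[c]), probs)
    return events


def _forced_change(
    rng: np.random.Generator, states: np.ndarray, comp: np.ndarray
) -> np.ndarray:
    """Resample each state to a *different* residue, proportional to ``comp``."""
    out = states.copy()
    pending = np.ones(states.shape, dtype=bool)
    cum = np.cumsum(comp)
    # rejection sampling; acceptance chance is 1 - comp[state] per round
    for _ in range(200):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        draw = np.searchsorted(cum, rng.random(idx.size), side="right")
        accept = draw != states[idx]
        out[idx[accept]] = draw[accept]
        pending[idx[accept]] = False
    return out


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One draw per row of a (L, k) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return np.argmin(u[:, None] >= cum, axis=1)


def simulate_null_alignment(tree: PhyloTree, aln: Alignment, seed: int) -> Alignment:
    """Evolve every column independently down the tree: the structure-free null.

    Each column re-evolves from a root drawn from the alignment-wide residue
    composition, with exactly its Fitch substitution count worth of forced
    substitution events placed on branches proportionally to branch length.
    Gap/N positions are copied verbatim from the input, so the null alignment
    shares the input's gap structure and per-column variability but no
    pair-specific covariation.
    """
    rng = np.random.default_rng(seed)
    mat = aln.to_matrix()
    order = _leaf_order_for(tree, aln)
    comps = _global_composition(aln)
    comp = comps[0]
    subs = fitch_counts(tree, aln)
    events = _place_events(rng, tree, subs)
    L = aln.length
    states = np.zeros((tree.n_nodes, L), dtype=np.int64)
    preorder = tree.preorder()
    root = preorder[0]
    states[root] = _sample_categorical(rng, comps)
    for node in preorder[1:]:
        state = states[tree.parent[node]].copy()
        remaining = events[node].copy()
        while True:
            hit = np.flatnonzero(remaining > 0)
            if hit.size == 0:
                break
            state[hit] = _forced_change(rng, state[hit], comp)
            remaining[hit] -= 1
        states[node] = state
    rows: list[str] = [""] * aln.n_seqs
    for leaf, row_idx in enumerate(order):
        orig = aln.rows[row_idx]
        sim = states[leaf]
        rows[row_idx] = "".join(
            orig[c] if mat[row_idx, c] == 4 else _RESIDUES[sim[c]] for c in range(L)
        )
    return Alignment(
        names=list(aln.names),
        rows=rows,
        ss_cons=aln.ss_cons,
        column_map=list(aln.column_map) if aln.column_map else None,
    )


@dataclass
class NullDistribution:
    """Pooled null covariation scores with an exponential upper-tail fit.

    p-values are empirical with a pseudocount, ``p = (k + 1) / (M + 1)`` for
    ``k`` null scores >= the observed score, floored at ``1 / (M + 1)``;
    beyond the sampled maximum the fitted exponential tail extrapolates
    (never above the empirical floor).

    Covariation statistics on small alignments are discrete (e.g. every pair
    involving an invariant column scores 0), and the plain empirical p-value
    is then badly conservative: the whole tie atom maps to its upper bound.
    ``survival`` therefore accepts per-query uniform draws ``u`` to break
    ties randomly, ``p = (k_> + u (k_= + 1)) / (M + 1)`` — the randomized
    probability integral transform, exactly Uniform(0,1) under the null —
    clipped below at the ``1/(M+1)`` resolution floor. Without ``u`` the
    deterministic conservative form is used.
    """

    scores: np.ndarray  # sorted ascending
    tail_threshold: float | None = None
    tail_rate: float | None = None
    tail_mass: float | None = None  # fraction of null scores >= tail_threshold

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if self.scores.size < 100:
            raise ValueError("null distribution needs at least 100 scores")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("null scores must be finite")

    @property
    def m(self) -> int:
        return int(self.scores.size)

    def survival(self, score, u=None) -> np.ndarray | float:
        """Empirical p-value(s) for the given score(s).

        ``u``: optional uniform draw(s) in [0, 1), same shape as ``score``,
        enabling randomized tie-breaking (see class docstring).
        """
        score_arr = np.atleast_1d(np.asarray(score, dtype=float))
        k_ge = self.m - np.searchsorted(self.scores, score_arr, side="left")
        if u is None:
            p = (k_ge + 1.0) / (self.m + 1.0)
        else:
            u_arr = np.broadcast_to(np.asarray(u, dtype=float), score_arr.shape)
            k_gt = self.m - np.searchsorted(self.scores, score_arr, side="right")
            n_tied = k_ge - k_gt
            p = (k_gt + u_arr * (n_tied + 1.0)) / (self.m + 1.0)
            p = np.maximum(p, 1.0 / (self.m + 1.0))
        if self.tail_rate is not None:
            beyond = score_arr > self.scores[-1]
            if beyond.any():
                tail = self.tail_mass * np.exp(
                    -self.tail_rate * (score_arr[beyond] - self.tail_threshold)
                )
                p[beyond] = np.minimum(p[beyond], np.maximum(tail, P_FLOOR))
        p = np.clip(p, P_FLOOR, 1.0)
        return p if np.ndim(score) else float(p[0])


def fit_exponential_tail(null: NullDistribution, tail_fraction: float = 0.05) -> None:
    """Fit an exponential to the top ``tail_fraction`` of null scores (MLE:
    rate = 1 / mean excess over the threshold) for extrapolation."""
    scores = null.scores
    k = max(int(np.ceil(tail_fraction * scores.size)), 10)
    threshold = scores[-k]
    excess = scores[-k:] - threshold
    mean_excess = float(excess.mean())
    if mean_excess <= 0:
        return  # degenerate tail; empirical floor only
    null.tail_threshold = float(threshold)
    null.tail_rate = 1.0 / mean_excess
    null.tail_mass = k / (scores.size + 1.0)


def build_null_distribution(
    tree: PhyloTree,
    aln: Alignment,
    n_aln: int = 20,
    seed: int = 42,
    apc: bool = True,
) -> NullDistribution:
    """Pool all-pairs scores from ``n_aln`` simulated null alignments."""
    pooled: list[np.ndarray] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_aln) % (2**31)
    for s in child_seeds:
        null_aln = simulate_null_alignment(tree, aln, int(s))
        g = score_all_pairs(null_aln, apc=apc)
        iu = np.triu_indices(g.shape[0], k=1)
        vals = g[iu]
        pooled.append(vals[np.isfinite(vals)])
    scores = np.concatenate(pooled)
    if scores.size < 100:
        raise ValueError(
            "null pool too small; increase n_aln so n_aln * n_pairs >= 100"
        )
    if np.allclose(scores, scores[0]):
        raise ValueError(
            "degenerate null distribution (all scores equal); increase n_aln "
            "or check the alignment for variation"
        )
    null = NullDistribution(scores=scores)
    fit_exponential_tail(null)
    return null


def pair_pvalue(score: float, null: NullDistribution, u: float | None = None) -> float:
    """Empirical p-value of a covariation score against the null pool.

    ``u`` in [0, 1) enables randomized tie-breaking; omit it for the
    deterministic (conservative, exactly score-monotone) form.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return float(null.survival(score, u=u))


# ---------------------------------------------------------------------------
# covariation power


@dataclass
class PowerCurve:
    """Monotone map from substitution count to detection probability.

    ``substitutions`` and ``power`` are matching arrays; lookups interpolate
    linearly and clamp to the calibrated range (so large counts return the
    plateau value and 0 substitutions return 0).
    """

    substitutions: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.substitutions = np.asarray(self.substitutions, dtype=float)
        self.power = np.clip(np.asarray(self.power, dtype=float), 0.0, 1.0)
        if self.substitutions.size != self.power.size or self.substitutions.size == 0:
            raise ValueError("substitutions and power must be equal-length, non-empty")
        if np.any(np.diff(self.substitutions) <= 0):
            raise ValueError("substitution grid must be strictly increasing")
        if np.any(np.diff(self.power) < -1e-12):
            raise ValueError("power must be non-decreasing")

    def __call__(self, substitutions) -> np.ndarray | float:
        s = np.asarray(substitutions, dtype=float)
        out = np.interp(s, self.substitutions, self.power)
        out = np.clip(out, 0.0, 1.0)
        return out if np.ndim(substitutions) else float(out)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"substitutions": self.substitutions, "power": self.power}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PowerCurve":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            substitutions=df["substitutions"].to_numpy(),
            power=df["power"].to_numpy(),
        )


def calibrate_power_curve(
    tree_ensemble,
    sim_params,
    seed: int = 42,
    n_alignments: int = 30,
    min_bin: int = 50,
) -> PowerCurve:
    """Self-calibrate power(substitutions) on the structured simulator.

    Simulates structure-constrained alignments, runs the standard pair-level
    analysis (NJ tree, phylogenetic null, two-set pair E-values), and records
    for every truly paired column duo whether it reached pair E-value < 0.05.
    Detection rates are binned by substitution count (adjacent bins widened
    until each holds ``min_bin`` pairs), made monotone by isotonic
    regression, and anchored at power(0) = 0 — no variation, no detection.

    ``tree_ensemble`` may be a list of :class:`PhyloTree` to cycle through,
    or None to sample a fresh tree per alignment from ``sim_params``.
    """
    from sklearn.isotonic import IsotonicRegression

    from helixcov import aggregation, simulate as sim_mod

    rng_seeds = np.random.SeedSequence(seed).generate_state(n_alignments) % (2**31)
    subs_obs: list[int] = []
    detected: list[bool] = []
    for rep, s in enumerate(rng_seeds):
        params = sim_mod.replace_params(sim_params, seed=int(s))
        if tree_ensemble:
            params = sim_mod.replace_params(params, tree=tree_ensemble[rep % len(tree_ensemble)])
        aln = sim_mod.simulate_structured_alignment(params)
        res = aggregation.analyze(
            aln, method="fisher", scope="two_set", seed=int(s) + 1, power_curve=_ZERO_CURVE
        )
        for (i, j), rec in res.pair_table.items():
            if rec.in_proposed_structure and rec.e_value is not None:
                subs_obs.append(rec.substitutions)
                detected.append(rec.e_value < 0.05)
    subs_arr = np.asarray(subs_obs, dtype=float)
    det_arr = np.asarray(detected, dtype=float)
    if subs_arr.size == 0:
        raise ValueError("no simulated pairs available for power calibration")
    # bin by substitution count, widening sparse bins
    order = np.argsort(subs_arr)
    subs_arr, det_arr = subs_arr[order], det_arr[order]
    centers: list[float] = []
    rates: list[float] = []
    sizes: list[int] = []
    start = 0
    uniq = np.unique(subs_arr)
    idx = np.searchsorted(subs_arr, uniq, side="right")
    for value, end in zip(uniq, idx):
        if end - start < min_bin and end < subs_arr.size:
            continue  # widen: merge into the next substitution-count bin
        if end - start < min_bin:
            warnings.warn(
                f"power calibration bin ending at {value} has only "
                f"{end - start} pairs (< {min_bin})",
                RuntimeWarning,
            )
        centers.append(float(np.mean(subs_arr[start:end])))
        rates.append(float(np.mean(det_arr[start:end])))
        sizes.append(end - start)
        start = end
    if not centers:
        centers = [float(subs_arr.mean())]
        rates = [float(det_arr.mean())]
        sizes = [subs_arr.size]
    iso = IsotonicRegression(increasing=True, y_min=0.0, y_max=1.0)
    fitted = iso.fit_transform(centers, rates, sample_weight=sizes)
    xs = np.asarray(centers, dtype=float)
    ys = np.asarray(fitted, dtype=float)
    if xs[0] > 0:
        xs = np.concatenate([[0.0], xs])
        ys = np.concatenate([[0.0], ys])
    else:
        ys[0] = 0.0
    # deduplicate any non-increasing x after anchoring
    keep = np.concatenate([[True], np.diff(xs) > 0])
    return PowerCurve(substitutions=xs[keep], power=np.maximum.accumulate(ys[keep]))


#: placeholder curve (power identically 0) used while calibrating power itself
_ZERO_CURVE = PowerCurve(substitutions=np.array([0.0, 1.0]), power=np.array([0.0, 0.0]))


def power_of_pair(substitutions: int, curve: PowerCurve) -> float:
    """Detection power for a pair with the given substitution count."""
    if substitutions < 0:
        raise ValueError("substitutions must be non-negative")
    return float(curve(substitutions))
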