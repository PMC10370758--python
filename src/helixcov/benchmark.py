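"""Sensitivity/specificity benchmarking of helix-level covariation calls.

Positives (structure-constrained simulations) and decoys (phylogeny-only
simulations carrying a transferred structure) are pushed through the
analyzer; the pooled, E-value-ranked helices yield sensitivity curves
against mean false positives per query alignment, FDR curves, E-value
calibration tables and null-uniformity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from helixcov import aggregation
from helixcov.msa_io import Alignment


def simulate_benchmark_sets(
    n_positives: int,
    n_decoys: int,
    seed: int = 42,
    **param_changes,
) -> tuple[list[Alignment], list[Alignment]]:
    """Simulate benchmark inputs: structure-constrained positives and
    phylogeny-only decoys, each alignment with its own random structure and
    tree drawn from the seed stream."""
    from helixcov import simulate as sim_mod

    seeds = np.random.SeedSequence(seed).generate_state(n_positives + n_decoys) % (2**31)
    positives = [
        sim_mod.simulate_structured_alignment(
            sim_mod.default_params(seed=int(s), **param_changes)
        )
        for s in seeds[:n_positives]
    ]
    decoys = [
        sim_mod.simulate_decoy_alignment(
            sim_mod.default_params(seed=int(s), **param_changes)
        )
        for s in seeds[n_positives:]
    ]
    return positives, decoys


@dataclass
class BenchmarkRecord:
    """One annotated helix from one alignment under one aggregation method."""

    alignment_id: str
    helix_id: int
    truth: str  # 'positive' or 'decoy' — from the generating set, never inferred
    method: str
    e_value: float
    p_aggregated: float
    n_pairs: int
    n_significant_pairs: int
    k1_support: bool
    k2_support: bool

    def __post_init__(self) -> None:
        if self.truth not in ("positive", "decoy"):
            raise ValueError("truth must be 'positive' or 'decoy'")
        if self.e_value <= 0:
            raise ValueError("e_value must be > 0")


def run_benchmark(
    positives: list[Alignment],
    decoys: list[Alignment],
    methods=("lancaster",),
    seed: int = 42,
    **analyze_options,
) -> list[BenchmarkRecord]:
    """Analyze every alignment and emit one record per helix per method.

    Failing alignments are skipped with a warning; more than 10% failures
    aborts the run. Deterministic given the seed.
    """
    if not positives or not decoys:
        raise ValueError("need at least one positive and one decoy alignment")
    if isinstance(methods, str):
        methods = (methods,)
    records: list[BenchmarkRecord] = []
    n_failed = 0
    n_total = len(positives) + len(decoys)
    labelled = [("positive", aln) for aln in positives] + [
        ("decoy", aln) for aln in decoys
    ]
    seeds = np.random.SeedSequence(seed).generate_state(n_total) % (2**31)
    for idx, ((truth, aln), aln_seed) in enumerate(zip(labelled, seeds)):
        aln_id = f"{truth}_{idx}"
        try:
            res = aggregation.analyze(
                aln, method=tuple(methods), seed=int(aln_seed), **analyze_options
            )
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            warnings.warn(f"alignment {aln_id} failed: {exc}", RuntimeWarning)
            if n_failed > 0.1 * n_total:
                raise RuntimeError(
                    f"more than 10% of alignments failed ({n_failed}/{n_total})"
                ) from exc
            continue
        for r in res.helix_results:
            records.append(
                BenchmarkRecord(
                    alignment_id=aln_id,
                    helix_id=r.helix_id,
                    truth=truth,
                    method=r.method,
                    e_value=max(r.e_value, 1e-300),
                    p_aggregated=r.p_aggregated,
                    n_pairs=r.n_pairs,
                    n_significant_pairs=r.n_significant_pairs,
                    k1_support=r.k_support(1),
                    k2_support=r.k_support(2),
                )
            )
    return records


def _single_method(records: list[BenchmarkRecord], method: str | None) -> list[BenchmarkRecord]:
    methods = {r.method for r in records}
    if method is None:
        if len(methods) > 1:
            raise ValueError(
                f"records mix methods {sorted(methods)}; pass method=..."
            )
        return list(records)
    return [r for r in records if r.method == method]


def n_decoy_alignments(records: list[BenchmarkRecord]) -> int:
    return len({r.alignment_id for r in records if r.truth == "decoy"})


def _fp_cutoff(decoy_e_sorted: np.ndarray, target_count: float) -> float:
    """E-value cutoff at which the decoy count equals ``target_count``,
    interpolating in log-E between adjacent decoy order statistics."""
    m = decoy_e_sorted.size
    if target_count >= m:
        return float("inf")
    if target_count < 1.0:
        # below the smallest decoy: admit only strictly smaller E-values
        return float(decoy_e_sorted[0]) * (1.0 - 1e-12)
    k = int(np.floor(target_count))
    frac = target_count - k
    lo = np.log(decoy_e_sorted[k - 1])
    hi = np.log(decoy_e_sorted[min(k, m - 1)])
    return float(np.exp(lo + frac * (hi - lo)))


def sensitivity_curve(
    records: list[BenchmarkRecord],
    fp_grid=None,
    method: str | None = None,
) -> list[tuple[float, float]]:
    """Fraction of positive helices detected at each mean-false-positives-per-
    alignment threshold (false positives normalised per decoy alignment)."""
    recs = _single_method(records, method)
    if fp_grid is None:
        fp_grid = np.logspace(-4, 0, 33)
    decoy_e = np.sort([r.e_value for r in recs if r.truth == "decoy"])
    pos_e = np.asarray([r.e_value for r in recs if r.truth == "positive"])
    if decoy_e.size == 0:
        raise ValueError("no decoy records; cannot set false-positive thresholds")
    if pos_e.size == 0:
        raise ValueError("no positive records")
    n_dec_aln = n_decoy_alignments(recs)
    out: list[tuple[float, float]] = []
    for f in fp_grid:
        cutoff = _fp_cutoff(decoy_e, f * n_dec_aln)
        sens = float(np.mean(pos_e <= cutoff))
        out.append((float(f), sens))
    return out


def unaggregated_operating_point(
    records: list[BenchmarkRecord], k: int = 1, method: str | None = None
) -> tuple[float, float]:
    """(mean false positives per alignment, sensitivity) of the baseline that
    calls a helix supported iff it has >= k significant base pairs."""
    recs = _single_method(records, method)
    flag = {1: (lambda r: r.k1_support), 2: (lambda r: r.k2_support)}[k]
    n_dec_aln = n_decoy_alignments(recs)
    fp = sum(1 for r in recs if r.truth == "decoy" and flag(r)) / n_dec_aln
    pos = [r for r in recs if r.truth == "positive"]
    sens = sum(1 for r in pos if flag(r)) / len(pos)
    return fp, sens


def sensitivity_at(records, fp_per_alignment: float, method: str | None = None) -> float:
    """Sensitivity at one mean-false-positives-per-alignment threshold."""
    ((_, sens),) = sensitivity_curve(
        records, fp_grid=[fp_per_alignment], method=method
    )
    return sens


def fdr_curve(
    records: list[BenchmarkRecord],
    e_thresholds=None,
    method: str | None = None,
) -> list[tuple[float, float]]:
    """FDR(t) = decoy helices with E < t / all helices with E < t (NaN when
    no helix passes t)."""
    recs = _single_method(records, method)
    if e_thresholds is None:
        e_thresholds = np.logspace(-4, 1, 26)
    e = np.asarray([r.e_value for r in recs])
    is_decoy = np.asarray([r.truth == "decoy" for r in recs])
    out: list[tuple[float, float]] = []
    for t in e_thresholds:
        below = e < t
        total = int(below.sum())
        fdr = float(is_decoy[below].sum() / total) if total else float("nan")
        out.append((float(t), fdr))
    return out


def calibration_table(
    records: list[BenchmarkRecord],
    e_thresholds=None,
    method: str | None = None,
) -> list[tuple[float, float]]:
    """(estimated E threshold, observed mean decoy helices per decoy alignment
    at E <= threshold). A calibrated method gives observed ~= threshold."""
    recs = _single_method(records, method)
    if e_thresholds is None:
        e_thresholds = np.logspace(-4, 0, 17)
    decoy_e = np.asarray([r.e_value for r in recs if r.truth == "decoy"])
    n_dec_aln = n_decoy_alignments(recs)
    if n_dec_aln == 0:
        raise ValueError("no decoy alignments")
    return [
        (float(t), float((decoy_e <= t).sum() / n_dec_aln)) for t in e_thresholds
    ]


def uniformity_test(pvalues) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against Uniform(0, 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a meaningful KS test")
    res = sps.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)
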