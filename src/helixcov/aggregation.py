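"""Helix-level p-value aggregation: the core statistical machinery.

Per-base-pair covariation p-values ``p_1 .. p_N`` within one helix are
combined into a single helix p-value by one of four methods:

* **Fisher** — ``T = sum -2 ln p_n`` is chi-squared with 2N degrees of
  freedom under the null of independent uniform p-values.
* **Lancaster** — each p-value carries a positive integer weight ``w_n``
  (here: the pair's Fitch substitution count);
  ``T = sum InvCDF_{chi2(w_n)}(1 - p_n)`` is chi-squared with ``sum w_n``
  degrees of freedom. All weights equal to 2 recovers Fisher exactly.
* **weighted-Fisher** — Lancaster generalised to real weights via the Gamma
  family: ``T = sum InvCDF_{Gamma(w_n/2, rate 1/2)}(1 - p_n)`` is
  Gamma(sum w_n / 2, rate 1/2). Weights come from covariation power,
  normalised so that ``sum w_n = 2N``.
* **Šidák** — depends only on the minimum p-value:
  ``p = 1 - (1 - p_min)^N``, the Bonferroni-like order-statistic test.

Helix p-values become E-values by multiplying by the number of helices in
the proposed structure; base-pair p-values become E-values by multiplying by
the number of base pairs tested (all of them, or the proposed/not-proposed
sets separately under the two-set scheme).

The public entry point is the :class:`HelixCovariation` model, whose
``fit()`` returns a :class:`HelixCovariationResults` with per-helix results,
the per-pair table and a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from helixcov import covariation as cov
from helixcov import msa_io, phylo, structure as struct_mod
from helixcov.msa_io import Alignment, PairStats, PairStatsTable
from helixcov.structure import Helix, SecondaryStructure

METHODS = ("fisher", "lancaster", "wfisher", "sidak")

#: significance threshold used throughout for "significantly covarying"
SIGNIFICANCE = 0.05


def _validate_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no pairs to aggregate")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must be in (0, 1]")
    return p


def _finish(p: float) -> float:
    return float(min(max(p, cov.P_FLOOR), 1.0))


def aggregate_fisher(pvals) -> float:
    """Fisher's combined p-value: chi-square survival of ``sum -2 ln p``."""
    p = _validate_pvals(pvals)
    t = float(-2.0 * np.sum(np.log(p)))
    return _finish(stats.chi2.sf(t, df=2 * p.size))


def fisher_statistic(pvals) -> float:
    return float(-2.0 * np.sum(np.log(_validate_pvals(pvals))))


def aggregate_lancaster(pvals, weights) -> float:
    """Lancaster's weighted combination with non-negative integer weights.

    Zero-weight pairs (no substitutions) contribute neither to the statistic
    nor to the degrees of freedom; if every weight is zero the helix is
    uninformative and the aggregated p-value is 1.
    """
    p = _validate_pvals(pvals)
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights and pvals must have the same length")
    if np.any(w < 0) or np.any(w != np.round(w)):
        raise ValueError("Lancaster weights must be non-negative integers")
    active = w > 0
    if not active.any():
        warnings.warn("no informative pairs (all weights 0)", RuntimeWarning)
        return 1.0
    t = float(np.sum(stats.chi2.isf(p[active], df=w[active])))
    return _finish(stats.chi2.sf(t, df=float(w.sum())))


def lancaster_statistic(pvals, weights) -> float:
    p = _validate_pvals(pvals)
    w = np.asarray(weights, dtype=float)
    active = w > 0
    if not active.any():
        return 0.0
    return float(np.sum(stats.chi2.isf(p[active], df=w[active])))


def aggregate_weighted_fisher(pvals, weights) -> float:
    """Gamma-family generalisation of Lancaster to arbitrary real weights >= 0."""
    p = _validate_pvals(pvals)
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights and pvals must have the same length")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weighted-Fisher weights must be finite and >= 0")
    active = w > 0
    if not active.any():
        warnings.warn("no informative pairs (all weights 0)", RuntimeWarning)
        return 1.0
    t = float(np.sum(stats.gamma.isf(p[active], a=w[active] / 2.0, scale=2.0)))
    return _finish(stats.gamma.sf(t, a=float(w.sum()) / 2.0, scale=2.0))


def wfisher_statistic(pvals, weights) -> float:
    p = _validate_pvals(pvals)
    w = np.asarray(weights, dtype=float)
    active = w > 0
    if not active.any():
        return 0.0
    return float(np.sum(stats.gamma.isf(p[active], a=w[active] / 2.0, scale=2.0)))


def aggregate_sidak(pvals) -> float:
    """Šidák's minimum-p test: ``1 - (1 - p_min)^N``, stable for small p_min."""
    p = _validate_pvals(pvals)
    pmin = float(p.min())
    if pmin >= 1.0:
        return 1.0
    return _finish(-math.expm1(p.size * math.log1p(-pmin)))


def power_to_weights(powers) -> np.ndarray:
    """weighted-Fisher weights ``w_n = 2 power_n / <power>`` (sum = 2N)."""
    pw = np.asarray(powers, dtype=float)
    if pw.size == 0:
        raise ValueError("need at least one power value")
    if np.any(pw < 0) or np.any(pw > 1):
        raise ValueError("powers must be in [0, 1]")
    mean = pw.mean()
    if mean == 0.0:
        warnings.warn("all powers are 0; weights are all 0", RuntimeWarning)
        return np.zeros_like(pw)
    return 2.0 * pw / mean


def helix_evalues(p_aggs, n_helices: int) -> list[float]:
    """Helix E-values: aggregated p-value times the number of helices.

    E-values carry expected-count semantics and are deliberately not capped
    at 1.
    """
    p_list = list(p_aggs)
    if not 1 <= len(p_list) <= n_helices:
        raise ValueError("need 1 <= len(p_aggs) <= n_helices")
    return [float(p) * n_helices for p in p_list]


def pair_evalues(table: PairStatsTable, scope: str = "two_set") -> PairStatsTable:
    """Attach E-values to a per-pair table.

    ``two_set``: pairs in the proposed structure are corrected by the number
    of proposed pairs, the remaining tested pairs by their own count (two
    separate hypothesis sets). ``one_set``: every pair is corrected by the
    total number of tested pairs.
    """
    if scope not in ("one_set", "two_set"):
        raise ValueError(f"scope must be 'one_set' or 'two_set', got {scope!r}")
    keys = list(table.records)
    proposed = [k for k in keys if table[k].in_proposed_structure]
    others = [k for k in keys if not table[k].in_proposed_structure]
    if scope == "two_set" and not proposed:
        raise ValueError("two_set correction requires a proposed structure")
    out: dict[tuple[int, int], PairStats] = {}
    for key, rec in table.items():
        if scope == "one_set":
            n_set = len(keys)
        else:
            n_set = len(proposed) if rec.in_proposed_structure else len(others)
        out[key] = PairStats(
            score=rec.score,
            p_value=rec.p_value,
            substitutions=rec.substitutions,
            power=rec.power,
            in_proposed_structure=rec.in_proposed_structure,
            e_value=rec.p_value * n_set,
        )
    return PairStatsTable(records=out)


def k_unaggregated_support(pair_e_values, k: int = 1) -> bool:
    """True iff at least k pairs are individually significant (E < 0.05)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    e = np.asarray(list(pair_e_values), dtype=float)
    return int(np.sum(e < SIGNIFICANCE)) >= k


# ---------------------------------------------------------------------------
# model / results


@dataclass
class HelixResult:
    """Aggregation outcome for one helix under one method."""

    helix_id: int
    method: str
    n_pairs: int
    statistic: float
    p_aggregated: float
    e_value: float
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    pair_breakdown: list[tuple[tuple[int, int], float, float]] = field(default_factory=list)
    n_significant_pairs: int = 0

    def k_support(self, k: int = 1) -> bool:
        return self.n_significant_pairs >= k


class HelixCovariation:
    """Helix-level covariation model for one annotated alignment.

    Parameters
    ----------
    alignment : Alignment
        Gapped RNA alignment; must carry an SS_cons consensus structure
        unless ``pair_stats`` is supplied with flagged structure pairs.
    pair_stats : PairStatsTable, optional
        Externally computed per-pair statistics (1-based original columns).
        When given, the tree/null/power machinery is bypassed entirely.
    method : str or sequence of str
        One of ``fisher``, ``lancaster``, ``wfisher``, ``sidak``, or ``all``.
    scope : str
        ``two_set`` (default) or ``one_set`` base-pair E-value correction.
    max_gap_frac : float
        Columns with a larger gap fraction are removed before analysis.
    n_null : int
        Number of simulated null alignments pooled for the empirical null.
    apc : bool
        Apply the average product correction to G scores.
    power_curve : PowerCurve, optional
        Pre-calibrated power curve; if absent and the weighted-Fisher method
        is requested, one is self-calibrated (slower).
    tree : PhyloTree, optional
        Working tree; inferred by neighbor joining when absent.
    seed : int
        Seed for the null simulation (and power calibration if triggered).
    """

    def __init__(
        self,
        alignment: Alignment,
        *,
        pair_stats: PairStatsTable | None = None,
        method="lancaster",
        scope: str = "two_set",
        max_gap_frac: float = 0.7,
        n_null: int = 20,
        apc: bool = True,
        power_curve: cov.PowerCurve | None = None,
        tree: phylo.PhyloTree | None = None,
        seed: int = 42,
    ) -> None:
        if isinstance(method, str):
            methods = METHODS if method == "all" else (method,)
        else:
            methods = tuple(method)
        for m in methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS} or 'all'")
        if scope not in ("one_set", "two_set"):
            raise ValueError("scope must be 'one_set' or 'two_set'")
        if alignment.ss_cons is None and pair_stats is None:
            raise ValueError(
                "alignment has no SS_cons consensus structure and no pair-stats "
                "table was supplied"
            )
        self.alignment = alignment
        self.pair_stats = pair_stats
        self.methods = methods
        self.scope = scope
        self.max_gap_frac = max_gap_frac
        self.n_null = n_null
        self.apc = apc
        self.power_curve = power_curve
        self.tree = tree
        self.seed = seed

    # -- pipeline pieces ----------------------------------------------------

    def _compute_pair_stats(self):
        """Filter, tree, null, p-values, powers; returns (filtered alignment,
        structure, helices, table keyed by original coordinates)."""
        filtered = msa_io.filter_gap_columns(self.alignment, self.max_gap_frac)
        if filtered.ss_cons is None:
            raise ValueError("alignment has no SS_cons consensus structure")
        struct = struct_mod.parse_wuss(filtered.ss_cons)
        helices = struct_mod.decompose_helices(struct)
        tree = self.tree or phylo.build_nj_tree(filtered)
        subs = phylo.fitch_counts(tree, filtered)
        null = cov.build_null_distribution(
            tree, filtered, n_aln=self.n_null, seed=self.seed, apc=self.apc
        )
        scores = cov.score_all_pairs(filtered, apc=self.apc)
        curve = self.power_curve
        if curve is None and any(m == "wfisher" for m in self.methods):
            from helixcov import simulate as sim_mod

            curve = cov.calibrate_power_curve(
                None,
                sim_mod.default_params(n_sequences=filtered.n_seqs),
                seed=self.seed + 1,
            )
        proposed = struct.pairs
        records: dict[tuple[int, int], PairStats] = {}
        L = filtered.length
        iu, ju = np.triu_indices(L, k=1)
        vals = scores[iu, ju]
        finite = np.isfinite(vals)
        # randomized tie-breaking keeps empirical p-values uniform under the
        # null despite the discreteness of G on small alignments
        tie_rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 0x7E5]).generate_state(1)[0]
        )
        pvals = null.survival(vals[finite], u=tie_rng.random(int(finite.sum())))
        for (i0, j0, s, p) in zip(iu[finite], ju[finite], vals[finite], pvals):
            i, j = int(i0) + 1, int(j0) + 1
            n_subs = int(subs[i - 1] + subs[j - 1])
            key = (filtered.original_column(i), filtered.original_column(j))
            records[key] = PairStats(
                score=float(s),
                p_value=float(p),
                substitutions=n_subs,
                power=cov.power_of_pair(n_subs, curve) if curve is not None else 0.0,
                in_proposed_structure=(i, j) in proposed,
            )
        return filtered, struct, helices, PairStatsTable(records=records)

    def _stats_from_table(self):
        """Helices and table when per-pair statistics are supplied externally."""
        aln = self.alignment
        if aln.ss_cons is not None:
            struct = struct_mod.parse_wuss(aln.ss_cons)
        else:
            pairs = {
                k for k, rec in self.pair_stats.items() if rec.in_proposed_structure
            }
            if not pairs:
                raise ValueError(
                    "pair-stats table flags no proposed-structure pairs and the "
                    "alignment carries no SS_cons"
                )
            length = max(j for _, j in pairs)
            struct = SecondaryStructure(pairs=pairs, length=length)
        helices = struct_mod.decompose_helices(struct)
        return aln, struct, helices, self.pair_stats

    def fit(self) -> "HelixCovariationResults":
        if self.pair_stats is not None:
            working, struct, helices, table = self._stats_from_table()
            col_of = lambda c: c  # external stats live in original coordinates
        else:
            working, struct, helices, table = self._compute_pair_stats()
            col_of = working.original_column
        table = pair_evalues(table, self.scope)
        n_helices = len(helices)
        results: list[HelixResult] = []
        for helix in helices:
            mapped = [(col_of(i), col_of(j)) for (i, j) in helix.pairs]
            stats_here = [(key, table[key]) for key in mapped if key in table]
            for method in self.methods:
                results.append(
                    self._aggregate_one(helix, mapped, stats_here, method, n_helices)
                )
        results.sort(key=lambda r: (r.e_value, r.helix_id, METHODS.index(r.method)))
        return HelixCovariationResults(
            model=self,
            helix_results=results,
            pair_table=table,
            n_helices=n_helices,
            structure=struct,
            working_alignment=working,
        )

    def _aggregate_one(self, helix, mapped, stats_here, method, n_helices) -> HelixResult:
        keys = [k for k, _ in stats_here]
        recs = [r for _, r in stats_here]
        if not recs:
            # every pair's statistic was undefined: uninformative helix
            return HelixResult(
                helix_id=helix.id,
                method=method,
                n_pairs=0,
                statistic=0.0,
                p_aggregated=1.0,
                e_value=float(n_helices),
                left_start=mapped[0][0],
                left_end=mapped[-1][0],
                right_start=mapped[-1][1],
                right_end=mapped[0][1],
            )
        pvals = np.array([r.p_value for r in recs])
        if method == "fisher":
            weights = np.full(pvals.size, 2.0)
            t = fisher_statistic(pvals)
            p_agg = aggregate_fisher(pvals)
        elif method == "lancaster":
            weights = np.array([float(r.substitutions) for r in recs])
            t = lancaster_statistic(pvals, weights)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p_agg = aggregate_lancaster(pvals, weights)
        elif method == "wfisher":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                weights = power_to_weights([r.power for r in recs])
                t = wfisher_statistic(pvals, weights)
                p_agg = aggregate_weighted_fisher(pvals, weights)
        else:  # sidak
            weights = np.ones(pvals.size)
            t = float(pvals.min())
            p_agg = aggregate_sidak(pvals)
        n_sig = sum(
            1 for r in recs if r.e_value is not None and r.e_value < SIGNIFICANCE
        )
        return HelixResult(
            helix_id=helix.id,
            method=method,
            n_pairs=len(recs),
            statistic=t,
            p_aggregated=p_agg,
            e_value=p_agg * n_helices,
            left_start=mapped[0][0],
            left_end=mapped[-1][0],
            right_start=mapped[-1][1],
            right_end=mapped[0][1],
            pair_breakdown=[
                (key, r.p_value, float(w)) for key, r, w in zip(keys, recs, weights)
            ],
            n_significant_pairs=n_sig,
        )


class HelixCovariationResults:
    """Fitted helix-covariation results: per-helix aggregation outcomes,
    the per-pair statistics table with E-values, and report writers."""

    def __init__(self, model, helix_results, pair_table, n_helices, structure, working_alignment):
        self.model = model
        self.helix_results: list[HelixResult] = helix_results
        self.pair_table: PairStatsTable = pair_table
        self.n_helices: int = n_helices
        self.structure: SecondaryStructure = structure
        self.working_alignment: Alignment = working_alignment

    def for_method(self, method: str) -> list[HelixResult]:
        return [r for r in self.helix_results if r.method == method]

    def significant_helices(self, method: str, threshold: float = SIGNIFICANCE):
        return [r for r in self.for_method(method) if r.e_value < threshold]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "helix_id": r.helix_id,
                    "left_start": r.left_start,
                    "left_end": r.left_end,
                    "right_start": r.right_start,
                    "right_end": r.right_end,
                    "n_pairs": r.n_pairs,
                    "n_significant_pairs": r.n_significant_pairs,
                    "method": r.method,
                    "statistic_T": r.statistic,
                    "p_aggregated": r.p_aggregated,
                    "e_value": r.e_value,
                }
                for r in self.helix_results
            ]
        )

    def to_helixcov(self, path) -> None:
        """Write the helix-level report TSV (one row per helix per method)."""
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.4g")

    def to_pair_tsv(self, path) -> None:
        msa_io.write_pair_stats_table(self.pair_table, path)

    def summary(self) -> str:
        lines = [
            "Helix-level covariation analysis",
            f"  alignment: {self.working_alignment.n_seqs} sequences x "
            f"{self.working_alignment.length} columns",
            f"  structure: {self.structure.n_pairs} base pairs in "
            f"{self.n_helices} helices",
            f"  methods:   {', '.join(self.model.methods)}   "
            f"scope: {self.model.scope}",
            "",
            f"{'helix':>5} {'method':>9} {'coords':>21} {'N':>3} {'sig':>3} "
            f"{'T':>10} {'p_agg':>10} {'E-value':>10}",
        ]
        for r in self.helix_results:
            coords = f"{r.left_start}-{r.left_end}:{r.right_start}-{r.right_end}"
            lines.append(
                f"{r.helix_id:>5} {r.method:>9} {coords:>21} {r.n_pairs:>3} "
                f"{r.n_significant_pairs:>3} {r.statistic:>10.4g} "
                f"{r.p_aggregated:>10.4g} {r.e_value:>10.4g}"
            )
        return "\n".join(lines)


def analyze(
    aln: Alignment,
    method="lancaster",
    scope: str = "two_set",
    **options,
) -> HelixCovariationResults:
    """Run the full per-alignment pipeline; see :class:`HelixCovariation`."""
    return HelixCovariation(aln, method=method, scope=scope, **options).fit()
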