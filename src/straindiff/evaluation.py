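"""Study-condition experiments: recovery, calibration and recall metrics.

Each function simulates data under the package's reference conditions
(200 kbp genome pairs at 12% pairwise divergence with the default event
mix, unless stated otherwise), runs the corresponding pipeline stage from
scratch and measures its performance against the simulator's truth log.
These experiments back both the test suite and the reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import orthology, regions as reg
from .plasticity import welch_one_sided
from .rrna import align_copies, copy_variants
from .simulate import AncestorSpec, EventSpec, TruthLog, evolve_pair, \
    generate_ancestor
from .sequtils import decode, random_sequence

REFERENCE_EVENTS = dict(substitution_rate=0.12, n_insertions=5,
                        n_deletions=3, n_divergent=2, n_translocations=1)


def _simulate(seed: int, genome_length: int = 200_000, gene_count: int = 180,
              **event_kwargs):
    rng = np.random.default_rng(seed)
    s1, s2 = (int(r.integers(0, 2 ** 31)) for r in rng.spawn(2))
    anc = generate_ancestor(AncestorSpec(genome_length=genome_length,
                                         gene_count=gene_count, rng_seed=s1))
    events = EventSpec(rng_seed=s2, **{**REFERENCE_EVENTS, **event_kwargs})
    a, b, log = evolve_pair(anc, events)
    return anc, a, b, log


def _classify(a, b, k_min=20, max_gap=5000):
    anchors = reg.find_anchors(a.sequence, b.sequence, k_min)
    blocks = reg.chain_anchors(anchors, a.sequence, b.sequence, max_gap)
    return reg.segment_and_classify(blocks, a, b)


def _event_recovered(event, calls, tolerance: int) -> bool:
    cls = event.expected_region_class()
    for r in calls:
        if r.region_class != cls:
            continue
        for iv_truth, iv_call in ((event.a_interval, r.a_interval),
                                  (event.b_interval, r.b_interval)):
            if not iv_truth or not iv_call:
                continue
            if min(iv_truth[1], iv_call[1]) <= max(iv_truth[0], iv_call[0]):
                continue
            err = max(abs(iv_truth[0] - iv_call[0]),
                      abs(iv_truth[1] - iv_call[1]))
            if err <= tolerance:
                return True
    return False


def region_recovery_experiment(n_replicates: int = 100, seed: int = 0,
                               boundary_tolerance: int = 40) -> dict:
    """Simulate ``n_replicates`` genome pairs under the reference event mix
    and measure (a) the fraction of structural events recovered with the
    correct region class and boundary error <= ``boundary_tolerance`` bp and
    (b) the fraction of replicates whose per-class region counts equal the
    truth-implied counts exactly."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31, size=n_replicates)
    n_events = n_recovered = n_count_match = 0
    for s in seeds:
        _, a, b, log = _simulate(int(s))
        calls = _classify(a, b)
        counts = reg.class_counts(calls)
        expected = log.expected_region_counts()
        if all(counts[k] == expected[k] for k in expected):
            n_count_match += 1
        for e in log.structural():
            n_events += 1
            n_recovered += _event_recovered(e, calls, boundary_tolerance)
    return {
        "n_replicates": n_replicates,
        "n_events": n_events,
        "event_recovery_rate": n_recovered / n_events,
        "count_match_rate": n_count_match / n_replicates,
    }


def ani_divergence_experiment(rates=(0.02, 0.05, 0.10, 0.15),
                              n_seeds: int = 10, seed: int = 0,
                              genome_length: int = 200_000) -> dict:
    """Mean one-directional ANIb of substitution-only pairs per divergence
    rate; the expectation under the edit-identity model is 100*(1-rate)."""
    rng = np.random.default_rng(seed)
    out = {}
    for rate in rates:
        anis = []
        for s in rng.integers(0, 2 ** 31, size=n_seeds):
            _, a, b, _ = _simulate(int(s), genome_length=genome_length,
                                   substitution_rate=rate, n_insertions=0,
                                   n_deletions=0, n_divergent=0,
                                   n_translocations=0)
            anis.append(orthology.compute_anib(a, b).ani)
        out[rate] = float(np.mean(anis))
    return out


def ortholog_recall_experiment(n_seeds: int = 20, seed: int = 0,
                               genome_length: int = 50_000,
                               gene_count: int = 45) -> float:
    """Fraction of ancestor genes whose ortholog is recovered as the best
    hit at 12% pairwise divergence, averaged over seeds."""
    rng = np.random.default_rng(seed)
    recalls = []
    for s in rng.integers(0, 2 ** 31, size=n_seeds):
        _, a, b, _ = _simulate(int(s), genome_length=genome_length,
                               gene_count=gene_count, n_insertions=0,
                               n_deletions=0, n_divergent=0,
                               n_translocations=0)
        pairs = orthology.best_hits(a.proteome(), b.proteome())
        correct = sum(1 for p in pairs
                      if p.query_id.replace("A_", "")
                      == p.subject_id.replace("B_", ""))
        recalls.append(correct / len(a.proteome()))
    return float(np.mean(recalls))


def welch_type1_experiment(n_sims: int = 2000, n_per_group: int = 8,
                           alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the one-sided Welch test under the null
    (both groups from the same normal distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        x = rng.normal(0, 1, n_per_group)
        y = rng.normal(0, 1, n_per_group)
        rejections += welch_one_sided(x, y).p < alpha
    return rejections / n_sims


def welch_permutation_agreement(x=(3.0, 4.0, 5.0), y=(0.0, 1.0, 2.0)
                                ) -> dict:
    """One-sided Welch p against the exhaustive permutation p on a fully
    enumerable toy input (all 20 splits of 6 values into 3+3)."""
    x, y = list(x), list(y)
    res = welch_one_sided(x, y)
    pooled = x + y
    n = len(pooled)
    count = total = 0
    for combo in itertools.combinations(range(n), len(x)):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        total += 1
        count += welch_one_sided(xs, ys).t >= res.t - 1e-12
    return {"welch_p": res.p, "permutation_p": count / total,
            "enumeration_error": 1 / total}


def rrna_masking_experiment(n_sets: int = 100, seed: int = 0,
                            copy_length: int = 800) -> dict:
    """Simulate 3-copy gene sets with planted single-copy differences and
    measure whether every planted position is recovered as masked and the
    per-copy difference counts are exact."""
    rng = np.random.default_rng(seed)
    exact_sets = 0
    planted_total = masked_recovered = 0
    for _ in range(n_sets):
        template = decode(random_sequence(copy_length, 0.5, rng))
        counts = rng.integers(0, 5, size=3)
        positions = rng.choice(copy_length, size=int(counts.sum()),
                               replace=False)
        plan: dict[str, list[int]] = {}
        k = 0
        for i, c in enumerate(counts):
            plan[f"c{i + 1}"] = sorted(int(p) for p in
                                       positions[k:k + int(c)])
            k += int(c)
        copies = []
        for cid, pos in plan.items():
            s = list(template)
            for p in pos:
                s[p] = "ACGT"[(("ACGT".index(s[p])) + 1 + int(
                    rng.integers(0, 3))) % 4]
            copies.append((cid, "".join(s)))
        aln = align_copies(copies)
        report = copy_variants(aln)
        expected_counts = {cid: len(pos) for cid, pos in plan.items()}
        if report.per_copy_differences == expected_counts:
            exact_sets += 1
        planted = {p + 1 for pos in plan.values() for p in pos}
        planted_total += len(planted)
        masked_recovered += len(planted & set(report.masked_columns()))
    return {
        "n_sets": n_sets,
        "exact_count_rate": exact_sets / n_sets,
        "masked_recovery_rate": (masked_recovered / planted_total
                                 if planted_total else 1.0),
    }
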