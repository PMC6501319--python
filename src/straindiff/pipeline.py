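"""End-to-end orchestration of the comparison stages.

``run_all`` executes the stages in dependency order on a simulated genome
pair (simulate -> align/classify regions -> orthologs -> ANI ->
hydrogenase motif scan -> functional deltas) and writes every table plus a
run manifest (parameters, file checksums).  All randomness flows from one
root seed, split per stage; outputs carry no timestamps so reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import orthology, plasticity, regions as reg
from .genome import AnnotatedGenome
from .simulate import AncestorSpec, EventSpec, evolve_pair, generate_ancestor, \
    write_fixture

logger = logging.getLogger("straindiff.pipeline")

DEFAULT_CONFIG = {
    "simulate": {
        "genome_length": 120_000, "gene_count": 110, "gc_fraction": 0.44,
        "substitution_rate": 0.12, "n_insertions": 3, "n_deletions": 2,
        "n_divergent": 1, "n_translocations": 1,
        "island_length_range": [3000, 8000], "mobility_marker_prob": 0.5,
    },
    "regions": {"k_min": 20, "max_gap": 5000},
    "orthologs": {"min_coverage": 80.0, "max_e": 1e-5},
    "ani": {"fragment_length": 1020},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = {k: {**v} for k, v in DEFAULT_CONFIG.items()}
    for section, values in cfg.items():
        merged.setdefault(section, {}).update(values or {})
    return merged


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_pair(cfg: dict, seed: int):
    """Build ancestor + derived pair from the ``simulate`` config section."""
    sim = {**DEFAULT_CONFIG["simulate"], **cfg.get("simulate", {})}
    rng = np.random.default_rng(seed)
    seed_anc, seed_ev = (int(s.integers(0, 2 ** 31)) for s in rng.spawn(2))
    anc = generate_ancestor(AncestorSpec(
        genome_length=int(sim["genome_length"]),
        gene_count=int(sim["gene_count"]),
        gc_fraction=float(sim["gc_fraction"]),
        rng_seed=seed_anc))
    events = EventSpec(
        substitution_rate=float(sim["substitution_rate"]),
        n_insertions=int(sim["n_insertions"]),
        n_deletions=int(sim["n_deletions"]),
        n_divergent=int(sim["n_divergent"]),
        n_translocations=int(sim["n_translocations"]),
        island_length_range=tuple(sim["island_length_range"]),
        mobility_marker_prob=float(sim["mobility_marker_prob"]),
        rng_seed=seed_ev)
    a, b, truth = evolve_pair(anc, events)
    return anc, a, b, truth


def classify_regions(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome,
                     k_min: int = 20, max_gap: int = 5000,
                     imported_blocks=None) -> list[reg.RegionCall]:
    """Anchor, chain and classify; imported blocks (XMFA/backbone) may stand
    in for internal anchoring."""
    if imported_blocks is not None:
        blocks = blocks_from_raw(imported_blocks)
    else:
        anchors = reg.find_anchors(genome_a.sequence, genome_b.sequence, k_min)
        blocks = reg.chain_anchors(anchors, genome_a.sequence,
                                   genome_b.sequence, max_gap)
    return reg.segment_and_classify(blocks, genome_a, genome_b)


def blocks_from_raw(raw_blocks) -> list[reg.AlignmentBlock]:
    """Mark imported two-sided blocks as main-chain when they are collinear
    (order-consistent in both genomes); the rest become off-chain."""
    two_sided = [b for b in raw_blocks if b.a_interval and b.b_interval]
    two_sided.sort(key=lambda b: b.a_interval[0])
    # longest run of blocks increasing in b — simple LIS over block order
    best_chain: list = []
    n = len(two_sided)
    scores = [0.0] * n
    parents = [-1] * n
    for i, b in enumerate(two_sided):
        ln = b.a_interval[1] - b.a_interval[0]
        scores[i] = ln
        for j in range(i):
            if (two_sided[j].b_interval[1] <= b.b_interval[0]
                    and scores[j] + ln > scores[i]):
                scores[i] = scores[j] + ln
                parents[i] = j
    if n:
        i = int(np.argmax(scores))
        while i != -1:
            best_chain.append(i)
            i = parents[i]
        best_chain.reverse()
    chain_set = set(best_chain)
    out = []
    for i, b in enumerate(two_sided):
        out.append(reg.AlignmentBlock(b.a_interval, b.b_interval, b.strand,
                                      b.identity, on_main_chain=i in chain_set))
    return out


def run_all(config: dict, out_dir, seed: int = 0,
            stages: list[str] | None = None) -> dict:
    """Run the pipeline on a simulated pair; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_stages = ["simulate", "classify-regions", "orthologs", "ani",
                  "func-delta"]
    stages = stages or all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    manifest: dict = {"seed": seed, "stages": [], "parameters": config,
                      "outputs": {}}

    if "simulate" not in stages and any(
            s in stages for s in all_stages[1:]):
        raise ValueError("downstream stages require the simulate stage "
                         "(or run them directly through the library on "
                         "loaded genomes)")

    anc, ga, gb, truth = simulate_pair(config, seed)
    written = write_fixture((ga, gb), truth, out_dir / "fixture")
    manifest["stages"].append("simulate")
    manifest["outputs"].update(written)

    region_calls = None
    if "classify-regions" in stages:
        rcfg = {**DEFAULT_CONFIG["regions"], **config.get("regions", {})}
        region_calls = classify_regions(ga, gb, int(rcfg["k_min"]),
                                        int(rcfg["max_gap"]))
        sio.write_regions_csv(region_calls, out_dir / "regions.csv")
        reg.summarize_regions(region_calls).to_csv(
            out_dir / "region_summary.csv", index=False)
        manifest["stages"].append("classify-regions")
        manifest["outputs"]["regions.csv"] = str(out_dir / "regions.csv")
        manifest["outputs"]["region_summary.csv"] = str(
            out_dir / "region_summary.csv")

    if "orthologs" in stages:
        ocfg = {**DEFAULT_CONFIG["orthologs"], **config.get("orthologs", {})}
        pairs = orthology.best_hits(ga.proteome(), gb.proteome(),
                                    float(ocfg["min_coverage"]),
                                    float(ocfg["max_e"]))
        if region_calls is not None:
            pairs = orthology.positional_orthologs(pairs, region_calls, ga, gb)
        orthology.orthologs_to_dataframe(pairs).to_csv(
            out_dir / "orthologs.csv", index=False)
        manifest["stages"].append("orthologs")
        manifest["outputs"]["orthologs.csv"] = str(out_dir / "orthologs.csv")

    if "ani" in stages:
        acfg = {**DEFAULT_CONFIG["ani"], **config.get("ani", {})}
        res = orthology.compute_anib_symmetric(
            ga, gb, fragment_length=int(acfg["fragment_length"]))
        pd.DataFrame([{
            "genome_a": ga.genome_id, "genome_b": gb.genome_id,
            "ani_percent": res.ani, "n_fragments": res.n_fragments,
            "n_retained": res.n_retained}]).to_csv(
            out_dir / "ani.csv", index=False)
        manifest["stages"].append("ani")
        manifest["outputs"]["ani.csv"] = str(out_dir / "ani.csv")

    if "func-delta" in stages:
        ta = plasticity.genome_annotation_table(ga)
        tb = plasticity.genome_annotation_table(gb)
        sets = plasticity.exclusive_annotation_sets(ta, tb)
        rows = [{"set": k, "ids": ";".join(sorted(v))} for k, v in sets.items()]
        pd.DataFrame(rows).to_csv(out_dir / "func_delta.csv", index=False)
        counts = {
            "transposases_a": plasticity.count_transposases(ta),
            "transposases_b": plasticity.count_transposases(tb)}
        pd.DataFrame([counts]).to_csv(out_dir / "transposases.csv",
                                      index=False)
        manifest["stages"].append("func-delta")
        manifest["outputs"]["func_delta.csv"] = str(out_dir / "func_delta.csv")
        manifest["outputs"]["transposases.csv"] = str(
            out_dir / "transposases.csv")

    manifest["checksums"] = {name: _checksum(Path(p))
                             for name, p in manifest["outputs"].items()}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
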