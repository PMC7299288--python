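"""End-to-end ground-truth benchmarks on synthetic data.

These drivers wire the full pipeline together — simulate subgenomes, build
the homeolog catalog by reciprocal best hit, simulate reads of known origin,
project alignments, classify, and score against truth — and are used by both
the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .catalog import build_catalog
from .classify import classify_sample
from .evaluate import classification_error
from .quantify import count_reads, distribute_common
from .synthesize import (
    SimConfig,
    project_alignments,
    simulate_reads,
    simulate_subgenomes,
)


def classification_benchmark(
    seeds,
    ploidy: int = 2,
    n_genes: int = 200,
    fragments: int = 100_000,
    snp_divergence: float = 0.0125,
    methods=("likelihood", "mismatch"),
    hexaploid_mode: str = "max_posterior",
    use_rbh_catalog: bool = True,
    denominator: str = "classified",
) -> dict:
    """Misclassification rates against ground truth, pooled over seeds.

    Returns per method: pooled error %, number of classified fragments, and
    the per-seed error list.
    """
    results = {
        m: {"wrong": 0, "denominator": 0, "per_seed": []} for m in methods
    }
    for seed in seeds:
        config = SimConfig(
            n_genes=n_genes,
            ploidy=ploidy,
            snp_divergence=snp_divergence,
            fragments_per_sample=fragments,
            seed=int(seed),
        )
        sim = simulate_subgenomes(config)
        catalog = (
            build_catalog(sim.sequences()) if use_rbh_catalog
            else sim.truth_catalog()
        )
        reads = simulate_reads(sim)
        alignments = project_alignments(reads, sim)
        truth = reads.truth(sim)
        for method in methods:
            rcs, _ = classify_sample(
                alignments, catalog, method=method,
                hexaploid_mode=hexaploid_mode,
            )
            report = classification_error(rcs, truth, denominator)
            results[method]["wrong"] += report.n_wrong
            results[method]["denominator"] += report.n_denominator
            results[method]["per_seed"].append(report.error_pct)
    for m in methods:
        r = results[m]
        r["error_pct"] = 100.0 * r["wrong"] / r["denominator"]
    return results


def phat_recovery(
    focal_fraction: float,
    seed: int,
    n_genes: int = 50,
    fragments: int = 10_000,
) -> dict:
    """Recover a planted mixing proportion via the full quantification path."""
    config = SimConfig(
        n_genes=n_genes,
        gene_length_range=(1000, 2000),
        focal_fraction=focal_fraction,
        fragments_per_sample=fragments,
        seed=int(seed),
    )
    sim = simulate_subgenomes(config)
    catalog = sim.truth_catalog()
    reads = simulate_reads(sim)
    alignments = project_alignments(reads, sim)
    rcs, _ = classify_sample(alignments, catalog)
    models = [m for ms in sim.transcript_models().values() for m in ms]
    base, common, _ = count_reads(rcs, alignments, models, catalog, "s1")
    counts = distribute_common(base, common)
    focal = sim.subgenomes[0]
    n = counts.values.sum()
    pooled = counts.xs(focal, axis=1, level="subgenome").values.sum() / n
    return {"phat": float(pooled), "n": float(n), "pi": focal_fraction}
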