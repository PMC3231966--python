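"""One-shot orchestration: simulate/load → mediators → indices →
correlations → null model → enrichment, written as a TSV report bundle.

All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence``, so any stage can be re-run in isolation and
a fixed (config, seed) pair yields a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    enrichment_pvalue,
    index_function_correlation,
    protein_pvalues,
    read_annotation_map,
    term_ratio,
    top_k,
)
from .graph_core import read_edge_list, write_edge_list
from .indices import compute_all
from .mediators import build_all, read_disease_sets, summarize
from .nullmodel import (
    NullModelSpec,
    correlation_matrix,
    index_distributions,
    randomization_test,
    upper_triangle,
)
from .synthetic import generate_instance

logger = logging.getLogger("medianet")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    Either file inputs (``ppi``, ``diseases``, optionally ``annotations``)
    or ``simulate: true`` with generator parameters.  Defaults follow the
    analysis conventions: n = 3 steps, thresholds 0.01 and 0.005, top-30
    rankings, 1000 null replicates.
    """

    outdir: str = "medianet_run"
    seed: int = 0
    # inputs
    simulate: bool = True
    ppi: str | None = None
    diseases: str | None = None
    annotations: str | None = None
    pairs: list = field(default_factory=lambda: [["H", "D"], ["H", "O"]])
    # generator parameters (used when simulate is true)
    num_nodes: int = 2000
    num_edges: int = 3500
    sizes: dict = field(default_factory=lambda: {"H": 9, "D": 44, "O": 20})
    mediators: dict = field(default_factory=lambda: {"HD": 16, "HO": 3, "shared": 9})
    # analysis parameters
    steps: int = 3
    thresholds: list = field(default_factory=lambda: [0.01, 0.005])
    top_k: int = 30
    null_reps: int = 1000
    histogram_bins: int = 20

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        # identifies the analysis, not where it is written
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Writes, under ``config.outdir``: the (possibly simulated) inputs, a
    network-size summary, per-network index tables, upper-triangular
    correlation matrices, null-model summaries, index histograms,
    enrichment tables, the config and a machine-readable manifest.  A stage
    failure aborts with the stage name; the manifest is only written on
    success, so a bundle without one is incomplete.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s) % (2**31)
        for name, s in zip(
            ("simulate", "null"), ss.generate_state(2, np.uint32)
        )
    }
    config.to_yaml(out / "config.yaml")

    stage = "inputs"
    try:
        if config.simulate:
            inst = generate_instance(
                num_nodes=config.num_nodes,
                num_edges=config.num_edges,
                sizes=config.sizes,
                mediators=config.mediators,
                seed=stage_seeds["simulate"],
            )
            ppi, ds, ann = inst.ppi, inst.disease_sets, inst.annotations
            write_edge_list(ppi, out / "edges.tsv")
            with open(out / "sets.tsv", "w", encoding="utf-8") as fh:
                for label in ds.labels:
                    for p in sorted(ds[label]):
                        fh.write(f"{p}\t{label}\n")
            with open(out / "truth.tsv", "w", encoding="utf-8") as fh:
                for pair in sorted(inst.truth_mediators):
                    for m in sorted(inst.truth_mediators[pair]):
                        fh.write(f"{m}\t{pair[0]}{pair[1]}\n")
            if ann is not None:
                with open(out / "ann.tsv", "w", encoding="utf-8") as fh:
                    for p in sorted(ann.proteins):
                        for t in sorted(ann.terms_of(p)):
                            fh.write(f"{p}\t{t}\n")
        else:
            if not config.ppi or not config.diseases:
                raise ValueError("non-simulated run needs 'ppi' and 'diseases' paths")
            ppi = read_edge_list(config.ppi)
            ds = read_disease_sets(config.diseases)
            ann = read_annotation_map(config.annotations) if config.annotations else None
        manifest["stages"][stage] = {
            "nodes": ppi.number_of_nodes(),
            "edges": ppi.number_of_edges(),
            "simulated": config.simulate,
        }

        stage = "mediators"
        pairs = [tuple(p) for p in config.pairs]
        results, total, shared = build_all(ppi, ds, pairs)
        _write_tsv(summarize(results, total), out / "summary.tsv", index=False)
        for pair, res in results.items():
            tag = "".join(pair)
            write_edge_list(res.mediator_network, out / f"network_{tag}.tsv")
            write_edge_list(res.mediator_subnetwork, out / f"subnetwork_{tag}.tsv",
                            dialect="sif")
        write_edge_list(total, out / "network_total.tsv")
        manifest["stages"][stage] = {
            "mediators": {"".join(p): len(r.mediators) for p, r in results.items()},
            "shared_mediators": len(shared),
        }

        stage = "indices"
        analysis_nets = {"".join(p): r.mediator_network for p, r in results.items()}
        analysis_nets["total"] = total
        tables = {}
        for name, net in analysis_nets.items():
            if net.number_of_nodes() < 3:
                logger.warning("skipping indices for %s (fewer than 3 nodes)", name)
                continue
            tables[name] = compute_all(
                net, n=config.steps, thresholds=tuple(config.thresholds)
            )
            _write_tsv(tables[name], out / f"indices_{name}.tsv")
        manifest["stages"][stage] = {"networks": sorted(tables)}

        stage = "correlations"
        for name, table in tables.items():
            _write_tsv(upper_triangle(correlation_matrix(table)),
                       out / f"correlations_{name}.tsv")
            hist = index_distributions(table, bins=config.histogram_bins)
            rows = []
            for col, (counts, edges) in hist.items():
                for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
                    rows.append({"index": col, "bin_low": lo, "bin_high": hi,
                                 "count": int(c)})
            _write_tsv(pd.DataFrame(rows), out / f"histograms_{name}.tsv", index=False)
        manifest["stages"][stage] = {"networks": sorted(tables)}

        stage = "nullmodel"
        null_info = {}
        for i, (name, net) in enumerate(sorted(analysis_nets.items())):
            if name not in tables:
                continue
            spec = NullModelSpec(
                N=net.number_of_nodes(),
                L=net.number_of_edges(),
                reps=config.null_reps,
                seed=(stage_seeds["null"] + i) % (2**31),
            )
            summary = randomization_test(
                spec, n=config.steps, thresholds=tuple(config.thresholds)
            )
            _write_tsv(summary.table, out / f"null_{name}.tsv", index=False)
            null_info[name] = {"N": spec.N, "L": spec.L, "reps": spec.reps}
        manifest["stages"][stage] = null_info

        stage = "enrichment"
        if ann is None:
            manifest["stages"][stage] = {"skipped": "no annotation map supplied"}
        else:
            for name, table in tables.items():
                background = set(table.index)
                rows = []
                corr_rows = []
                for col in table.columns:
                    top = top_k(table, col, k=config.top_k)
                    pvals = protein_pvalues(top, background, ann)
                    terms = set()
                    for p in top:
                        terms |= ann.terms_of(p)
                    for t in sorted(terms):
                        rows.append({
                            "index": col,
                            "term": t,
                            "ratio": term_ratio(top, t, ann),
                            "pvalue": enrichment_pvalue(top, t, background, ann),
                        })
                    sub = table.loc[top]
                    corr_rows.append({
                        "index": col,
                        "rho_pvalue_vs_index": index_function_correlation(
                            sub, pvals, col
                        ),
                    })
                _write_tsv(pd.DataFrame(rows), out / f"enrichment_{name}.tsv",
                           index=False)
                _write_tsv(pd.DataFrame(corr_rows),
                           out / f"enrichment_corr_{name}.tsv", index=False)
            manifest["stages"][stage] = {"top_k": config.top_k}
    except Exception:
        logger.error("pipeline stage %r failed", stage)
        (out / "INCOMPLETE").write_text(f"failed at stage: {stage}\n")
        raise

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    incomplete = out / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return manifest
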