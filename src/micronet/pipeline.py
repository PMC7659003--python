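"""End-to-end orchestration of the network-based perturbation analysis.

Stage order follows the method: count normalization and relative
abundances; per-taxon feature annotation (level, core/nR, differential
status) and the presence (Venn) partition; diversity indices; correlation
and co-occurrence clustering; per-condition ensemble gLV network inference
with coherence filtering; centralities and topological-niche scores over
the strength grid; motif census and significance per strength level; and a
PCA report.  Every written artifact carries the config hash and seed in a
comment header, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import abundance as ab
from . import cooccurrence as co
from . import glv
from . import motifs as mo
from . import topology as topo
from .config import PipelineConfig
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("micronet")

__all__ = ["PipelineResult", "run_pipeline", "pca_report"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    table_c: ab.AbundanceTable
    table_b: ab.AbundanceTable
    annotations: pd.DataFrame
    partition: tuple[set, set, set]
    diversity: pd.DataFrame
    clusters: list
    edges_c: list
    edges_b: list
    centralities_c: dict
    centralities_b: dict
    niche: pd.DataFrame
    motif_records: dict
    representative: dict
    pca_variance: np.ndarray
    pca_loadings: pd.DataFrame
    truth: object | None = None


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def _done(name: str, t0: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %s done in %.2fs %s", name, time.perf_counter() - t0, extra)


def run_pipeline(
    config: PipelineConfig | None = None,
    table_c: ab.AbundanceTable | None = None,
    table_b: ab.AbundanceTable | None = None,
    synthetic_config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on the given (or synthesized) paired tables.

    Without input tables, a synthetic dataset is generated from
    ``synthetic_config`` (or the study-shaped defaults) at the config seed.
    """
    cfg = config or PipelineConfig()
    alpha = cfg.thresholds.alpha
    truth = None
    if table_c is None or table_b is None:
        t0 = _stage("simulate")
        syn = synthetic_config or cfg.synthetic.to_synthetic_config()
        table_c, table_b, truth = generate_dataset(syn, seed=cfg.seed)
        _done("simulate", t0, taxa=table_c.n_taxa)

    t0 = _stage("normalize")
    if table_c.units == ab.COUNTS:
        # normalize the combined dataset so condition-specific taxa survive
        combined, _ = ab.normalize_counts(ab.merge_tables(table_c, table_b))
        rel = ab.to_relative(combined)
        rel_c, rel_b = rel.condition("C"), rel.condition("B")
    else:
        rel_c, rel_b = table_c, table_b
    _done("normalize", t0, taxa=rel_c.n_taxa)

    t0 = _stage("annotate")
    annotations = ab.annotate_taxa(rel_c, rel_b, alpha=alpha)
    partition = ab.presence_partition(rel_c, rel_b)
    div_rows = []
    for table, cond in ((rel_c, "C"), (rel_b, "B")):
        for sample in table.values.columns:
            col = table.values[sample].to_numpy()
            sh, inv, chao = ab.diversity_indices(col)
            div_rows.append(
                {"sample": sample, "condition": cond,
                 "shannon": sh, "inv_simpson": inv, "chao1": chao}
            )
    diversity = pd.DataFrame(div_rows).set_index("sample")
    _done("annotate", t0, taxa=len(annotations))

    t0 = _stage("correlate")
    clusters = co.build_cooccurrence_clusters(rel_c, rel_b, alpha=alpha)
    _done("correlate", t0, clusters=len(clusters))

    t0 = _stage("infer-network")
    rng = np.random.SeedSequence(cfg.seed).spawn(2)
    edges_c = glv.reliability_filter(
        glv.ensemble_infer(
            rel_c.condition("C"), cfg.ensemble.n_networks,
            cfg.ensemble.member_frac, cfg.ensemble.ridge,
            seed=rng[0],
        ),
        cfg.thresholds.coherence, alpha,
    )
    edges_b = glv.reliability_filter(
        glv.ensemble_infer(
            rel_b.condition("B"), cfg.ensemble.n_networks,
            cfg.ensemble.member_frac, cfg.ensemble.ridge,
            seed=rng[1],
        ),
        cfg.thresholds.coherence, alpha,
    )
    n_rel_c = sum(e.reliable for e in edges_c)
    n_rel_b = sum(e.reliable for e in edges_b)
    _done("infer-network", t0, reliable_C=n_rel_c, reliable_B=n_rel_b)

    t0 = _stage("topology")
    taxa = rel_c.taxa
    centralities_c: dict = {}
    centralities_b: dict = {}
    graphs_c: dict = {}
    graphs_b: dict = {}
    for level in cfg.strength_grid:
        for edges, out_prof, out_graph in (
            (edges_c, centralities_c, graphs_c),
            (edges_b, centralities_b, graphs_b),
        ):
            reliable = [e for e in edges if e.reliable]
            sub = reliable if level == "all" else glv.top_k_edges(edges, int(level))
            g = glv.to_digraph(sub)
            out_graph[level] = g
            out_prof[level] = topo.centralities(g, taxa)
    niche = topo.niche_table(centralities_b, centralities_c)
    _done("topology", t0, levels=len(cfg.strength_grid))

    t0 = _stage("motifs")
    motif_records: dict = {}
    representative: dict = {}
    motif_seeds = np.random.SeedSequence(cfg.seed + 1).spawn(2)
    for cond, graphs, sseq in (("C", graphs_c, motif_seeds[0]),
                               ("B", graphs_b, motif_seeds[1])):
        numeric_levels = [s for s in cfg.strength_grid if s != "all"]
        level_seeds = sseq.spawn(max(len(numeric_levels), 1) * len(cfg.motifs.sizes))
        si = 0
        for n in cfg.motifs.sizes:
            per_level = {}
            for level in numeric_levels:
                per_level[level] = mo.motif_significance(
                    graphs[level], n, n_random=cfg.motifs.n_random,
                    seed=level_seeds[si], z_threshold=cfg.thresholds.motif_z,
                    min_count=cfg.thresholds.motif_min_count,
                )
                si += 1
            motif_records[(cond, n)] = per_level
            if len(per_level) >= 3:
                representative[(cond, n)] = mo.representative_motifs(per_level)
    _done("motifs", t0, conditions=2)

    t0 = _stage("pca")
    pca_variance, pca_loadings = pca_report(rel_c, rel_b, annotations, clusters)
    _done("pca", t0)

    result = PipelineResult(
        cfg, rel_c, rel_b, annotations, partition, diversity, clusters,
        edges_c, edges_b, centralities_c, centralities_b, niche,
        motif_records, representative, pca_variance, pca_loadings, truth,
    )
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def pca_report(
    table_c: ab.AbundanceTable,
    table_b: ab.AbundanceTable,
    annotations: pd.DataFrame | None = None,
    clusters: list | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Centered PCA of the combined samples-by-taxa relative abundances.

    Returns (percent variance explained per component, loadings table).
    Loadings are annotated with differential status and a GxGyGz cluster
    code (before / anchor / after epochs) when annotations and clusters are
    supplied.
    """
    x = np.vstack([
        table_c.values.to_numpy(dtype=float).T,
        table_b.values.to_numpy(dtype=float).T,
    ])
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(x)
    variance = pca.explained_variance_ratio_ * 100.0
    loadings = pd.DataFrame(
        pca.components_[: min(5, n_comp)].T,
        index=table_c.taxa,
        columns=[f"PC{i + 1}" for i in range(min(5, n_comp))],
    )
    if annotations is not None:
        loadings["diff_status"] = annotations["diff_status"]
    if clusters:
        codes = {}
        for c in clusters:
            for t in c.members:
                before = c.label if c.epochs[t] in ("before", "both") else "-"
                after = c.label if c.epochs[t] in ("after", "both") else "-"
                anchor = c.label if t in c.anchors else "-"
                codes[t] = f"{before}{anchor}{after}"
        loadings["cluster_code"] = pd.Series(codes).reindex(loadings.index).fillna("")
    return variance, loadings


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def _write_tsv(frame: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t")


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    """Write every stage artifact as TSV/JSON with a config-hash header."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    header = f"micronet config_hash={cfg.hash()} seed={cfg.seed}"
    _write_tsv(result.annotations, out_dir / "annotations.tsv", header)
    _write_tsv(result.diversity, out_dir / "diversity.tsv", header)
    _write_tsv(co.clusters_frame(result.clusters), out_dir / "clusters.tsv", header)
    _write_tsv(glv.edges_frame(result.edges_c), out_dir / "edges_C.tsv", header)
    _write_tsv(glv.edges_frame(result.edges_b), out_dir / "edges_B.tsv", header)
    _write_tsv(result.niche, out_dir / "niche.tsv", header)
    motif_rows = []
    for (cond, n), per_level in result.motif_records.items():
        rep = result.representative.get((cond, n), set())
        for level, records in per_level.items():
            for r in records:
                motif_rows.append(
                    {"condition": cond, "n": n, "strength": level,
                     "canonical_id": r.canonical_id, "count": r.count_real,
                     "null_mean": r.null_mean, "null_sd": r.null_sd,
                     "z": r.z, "significant": r.significant,
                     "representative": r.canonical_id in rep}
                )
    _write_tsv(pd.DataFrame(motif_rows), out_dir / "motifs.tsv", header)
    _write_tsv(result.pca_loadings, out_dir / "pca_loadings.tsv", header)
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(result.pca_variance))],
         "variance_pct": result.pca_variance}
    ).to_csv(out_dir / "pca_variance.tsv", sep="\t", index=False)
    shared, c_only, b_only = result.partition
    (out_dir / "venn.json").write_text(
        pd.Series(
            {"shared": sorted(shared), "C_only": sorted(c_only),
             "B_only": sorted(b_only)}
        ).to_json()
    )
    (out_dir / "config.yaml").write_text(cfg.to_yaml())
    if result.truth is not None:
        (out_dir / "truth.json").write_text(result.truth.to_json())
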