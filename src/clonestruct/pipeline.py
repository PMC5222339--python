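"""End-to-end orchestration: discriminate -> diversity -> spatial ->
structure -> ordination/network, with a consolidated machine-readable
summary.

Each stage writes its own CSV/JSON artifacts into the output directory and
failures in one stage are recorded in a manifest rather than aborting the
rest, so any stage can be inspected or re-run in isolation.
"""

from __future__ import annotations

import json
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import __version__
from .genotype_io import GenotypeTable, complete_cases
from .discrimination import (identify_mlgs, allele_frequencies, p_gen,
                             p_sex, p_id, mlg_distance_matrix,
                             find_collapse_threshold, collapse_mll)
from .diversity import diversity_report
from .spatial import spatial_report
from .structure import dual_analysis, truncate_dataset
from .multivariate import (shared_allele_distance, dice_distance, pcoa,
                           build_network, mlg_site_composition)

logger = logging.getLogger("clonestruct")


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int
    n_perm_spatial: int = 1000
    n_perm_fis: int = 10_000
    n_perm_fst: int = 1000
    mll_threshold: int | None = None   # None: derive from the distance gap
    datasets: tuple[str, ...] = ("entire", "truncated")
    n_pcoa_axes: int = 2

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if min(self.n_perm_spatial, self.n_perm_fis, self.n_perm_fst) < 100:
            raise ValueError("permutation counts must be >= 100")


@dataclass
class PipelineResult:
    summary: dict
    manifest: dict[str, str] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def _register(result: PipelineResult, path: Path) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    result.manifest[path.name] = digest


def _matrix_csv(mat, path: Path) -> None:
    df = pd.DataFrame(mat.values, index=mat.populations,
                      columns=mat.populations)
    df.to_csv(path, float_format="%.6f")


def run_pipeline(table: GenotypeTable, config: PipelineConfig
                 ) -> PipelineResult:
    """Run every analysis stage on a genotype table and write the bundle.

    Outputs: mlg_assignments.csv, mlg_summary.csv, distance_matrix.csv,
    threshold.json, diversity_report.csv, pareto_points.csv,
    spatial_report.csv, fst_/dest_/fis CSVs, ld_tests.csv, ordination.csv,
    edges.csv, network.graphml, and summary.json (+ manifest with
    checksums).  Re-running with the same seed reproduces summary.json
    byte for byte.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(summary={})
    timings: dict[str, float] = {}
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_total": len(table),
        "sites": table.sites,
    }

    # --- clone discrimination ---------------------------------------
    t0 = time.perf_counter()
    cc = complete_cases(table)
    summary["n_complete"] = len(cc)
    partition = identify_mlgs(cc)
    dist = mlg_distance_matrix(partition, cc.loci)
    if config.mll_threshold is not None:
        threshold = config.mll_threshold
    elif partition.n_mlg >= 2:
        threshold = find_collapse_threshold(dist)
    else:
        threshold = 0
    partition = collapse_mll(partition, dist, threshold)
    summary["n_mlg"] = partition.n_mlg
    summary["n_mll"] = partition.n_mll
    summary["mll_threshold"] = threshold
    min_dist = int(dist.pairwise_values().min()) if partition.n_mlg > 1 \
        else None
    summary["min_inter_mlg_distance"] = min_dist

    freqs = allele_frequencies(cc, partition, scheme="genet-level")
    sizes = partition.mlg_sizes()
    summary["superclone"] = {
        "mlg": max(sizes, key=sizes.get),
        "share": max(sizes.values()) / len(cc),
    }
    summary["p_id_pooled"] = p_id(freqs.pooled())

    pd.DataFrame(
        [(sid, m, partition.mll_of[m])
         for sid, m in sorted(partition.mlg_of.items())],
        columns=["sample", "mlg", "mll"],
    ).to_csv(out / "mlg_assignments.csv", index=False)

    site_of = {s.id: s.site for s in cc.samples}
    comp = mlg_site_composition(partition, site_of)
    pooled = freqs.pooled()
    mlg_rows = []
    for mid in partition.mlg_ids:
        size = sizes[mid]
        pg = p_gen(partition.mlg_genotype[mid], pooled, cc.loci, 0.0)
        mlg_rows.append({
            "mlg": mid, "size": size,
            **{f"n_{s}": comp[mid].get(s, 0) for s in cc.sites},
            "p_gen": pg, "p_sex": p_sex(size, len(cc), pg),
        })
    pd.DataFrame(mlg_rows).to_csv(out / "mlg_summary.csv", index=False)
    pd.DataFrame(dist.matrix, index=dist.ids, columns=dist.ids
                 ).to_csv(out / "distance_matrix.csv")
    (out / "threshold.json").write_text(json.dumps(
        {"threshold": threshold, "min_inter_mlg_distance": min_dist},
        indent=2))
    timings["discriminate"] = time.perf_counter() - t0

    # --- clonal diversity --------------------------------------------
    t0 = time.perf_counter()
    try:
        div = diversity_report(cc, partition)
        rows = []
        ppoints = []
        for p in div.populations:
            rows.append({
                "population": p.population, "N": p.n, "N_MLG": p.n_mlg,
                "R": p.r, "G_O": p.g_o, "G": p.g, "ED_star": p.ed_star,
                "beta": p.beta, "beta_r2": p.beta_r2, "A_hat": p.a_hat,
                "H_O": p.h_o, "H_E": p.h_e,
            })
            if p.pareto_points is not None:
                for x, fr in p.pareto_points:
                    ppoints.append({"population": p.population,
                                    "size": int(x), "cum_fraction": fr})
        pd.DataFrame(rows).to_csv(out / "diversity_report.csv", index=False)
        pd.DataFrame(ppoints).to_csv(out / "pareto_points.csv", index=False)
        summary["diversity"] = rows
    except Exception as e:       # noqa: BLE001 - stage isolation
        result.failures["diversity"] = str(e)
    timings["diversity"] = time.perf_counter() - t0

    # --- spatial ------------------------------------------------------
    t0 = time.perf_counter()
    if any(s.has_coords for s in cc.samples):
        try:
            sp = spatial_report(cc, partition.mlg_of,
                                n_perm=config.n_perm_spatial,
                                seed=config.seed)
            sp_rows = [{
                "population": r.population, "Ac": r.ac, "p_Ac": r.p_ac,
                "Ee": r.ee, "p_Ee": r.p_ee, "morans_I": r.morans_i,
                "p_I": r.p_i, "n_permutations": r.n_permutations,
                "seed": r.seed} for r in sp]
            pd.DataFrame(sp_rows).to_csv(out / "spatial_report.csv",
                                         index=False)
            summary["spatial"] = sp_rows
        except Exception as e:   # noqa: BLE001
            result.failures["spatial"] = str(e)
    else:
        result.failures["spatial"] = "skipped: no coordinates"
    timings["spatial"] = time.perf_counter() - t0

    # --- population structure ----------------------------------------
    t0 = time.perf_counter()
    try:
        entire, truncated = dual_analysis(
            cc, partition, n_perm_fis=config.n_perm_fis,
            n_perm_fst=config.n_perm_fst, seed=config.seed)
        summary["structure"] = {}
        for rep in (entire, truncated):
            if rep.dataset_tag not in config.datasets:
                continue
            tag = rep.dataset_tag
            if rep.fst is not None:
                _matrix_csv(rep.fst, out / f"fst_{tag}.csv")
            if rep.dest is not None:
                _matrix_csv(rep.dest, out / f"dest_{tag}.csv")
            summary["structure"][tag] = {
                "fis": {p: {"value": r.multilocus, "p": r.p_value}
                        for p, r in rep.fis_by_pop.items()},
                "failures": rep.failures,
            }
            result.failures.update(
                {f"{tag}:{k}": v for k, v in rep.failures.items()})
        fis_rows = []
        for rep in (entire, truncated):
            for p, r in rep.fis_by_pop.items():
                fis_rows.append({"dataset": rep.dataset_tag,
                                 "population": p,
                                 "fis": r.multilocus, "p": r.p_value})
        pd.DataFrame(fis_rows).to_csv(out / "fis.csv", index=False)
        if truncated.ld_tests:
            pd.DataFrame([{
                "locus_a": t.locus_a, "locus_b": t.locus_b,
                "G": t.g_statistic, "p": t.p_value,
                "significant_bonferroni": t.significant_bonferroni,
            } for t in truncated.ld_tests]).to_csv(out / "ld_tests.csv",
                                                   index=False)
        summary["n_truncated"] = len(truncate_dataset(cc, partition))
    except Exception as e:       # noqa: BLE001
        result.failures["structure"] = str(e)
    timings["structure"] = time.perf_counter() - t0

    # --- multivariate -------------------------------------------------
    t0 = time.perf_counter()
    try:
        if partition.n_mlg >= 3:
            ids, dice = dice_distance(partition.mlg_genotype)
            ord_res = pcoa(dice, ids, n_axes=config.n_pcoa_axes)
            ord_df = pd.DataFrame(
                ord_res.coordinates,
                columns=[f"axis{i+1}" for i in
                         range(ord_res.coordinates.shape[1])])
            ord_df.insert(0, "mlg", ord_res.ids)
            ord_df.to_csv(out / "ordination.csv", index=False)
            summary["ordination_pct_variance"] = [
                float(v) for v in ord_res.percent_variance]
            ids2, das = shared_allele_distance(partition.mlg_genotype)
            net = build_network(das, ids2, node_sizes=sizes,
                                site_composition=comp)
            nx.write_graphml(net.graph, out / "network.graphml")
            pd.DataFrame(
                [(u, v, d["weight"])
                 for u, v, d in net.graph.edges(data=True)],
                columns=["mlg_a", "mlg_b", "distance"],
            ).to_csv(out / "edges.csv", index=False)
            summary["network"] = {"threshold": net.threshold,
                                  "n_edges": net.n_edges}
        else:
            result.failures["multivariate"] = "skipped: fewer than 3 MLGs"
    except Exception as e:       # noqa: BLE001
        result.failures["multivariate"] = str(e)
    timings["multivariate"] = time.perf_counter() - t0

    summary["failures"] = result.failures
    result.summary = summary
    # timings go to their own file so summary.json stays byte-identical
    # across reruns with the same seed
    (out / "timings.json").write_text(
        json.dumps({k: round(v, 3) for k, v in timings.items()}, indent=2))
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            _register(result, p)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
    return result
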