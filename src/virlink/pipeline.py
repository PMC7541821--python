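"""End-to-end orchestration: simulate (or load) -> sketch -> classify ->
cluster -> summarise -> test.

``run_pipeline`` executes every stage with a single seed and writes the
stage outputs plus a machine-readable ``report.json`` holding per-lineage
virus prevalence, the contingency tests, ANOVA/Tukey on per-SAG viral
contig counts, the inter-phylum cluster list, and the droplet co-sorting
expectation bounds.  Re-running with an identical configuration
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classify as clf
from . import cosort as cs
from . import network as net
from . import sketch as sk
from . import stats as vstats
from .synthetic import (SimulationConfig, emit_evidence_tables,
                        simulate_sag_set, taxonomy_table, write_sag_fastas)

__all__ = ["RunConfig", "run_pipeline", "evaluate_against_truth"]

log = logging.getLogger("virlink")


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one input mode is active: synthetic (``simulation`` config,
    the default) or real (``input_dir`` pointing at a directory with
    ``fasta/``, ``taxonomy.tsv`` and the evidence tables).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None
    out_dir: str = "virlink_out"
    seed: int = 1
    k: int = sk.DEFAULT_K
    sketch_size: int = sk.DEFAULT_SKETCH_SIZE
    hash_seed: int = sk.DEFAULT_HASH_SEED
    distance_threshold: float = 0.05
    clustering: str = "louvain"
    knn_k: int = 5
    alpha: float = 0.05
    lca_min_freq: float = 0.25
    viral_min_fraction: float = 0.25
    phage_lineages: tuple = vstats.DEFAULT_PHAGE_LINEAGES
    write_fasta: bool = True
    quiet: bool = False

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        for presentation in ("out_dir", "quiet", "write_fasta"):
            d.pop(presentation, None)
        blob = json.dumps(_as_jsonable(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, list):
        return [_round6(v) for v in x]
    return x


def make_training_set(seed: int = 97, n_per_class: int = 60) -> clf.TrainingSet:
    """Default kNN training set: a small noiseless synthetic community,
    labelled from its planted truth (dsDNA phage = viral; eukaryote and
    bacterial contigs = nonviral; ssDNA viruses are excluded because the
    features the kNN uses do not capture them — they are handled by the
    dedicated ssDNA rule)."""
    cfg = SimulationConfig(
        seed=seed,
        n_sags_per_lineage={"TrainA": 6, "TrainB": 6},
        lineage_grazing_rate={"TrainA": 4.0, "TrainB": 4.0},
        bacterial_prey_prob={"TrainA": 0.5, "TrainB": 0.5},
        plastidic_lineages=(),
        evidence_fp=0.0, evidence_fn=0.0, external_call_rate=0.0,
    )
    rng = np.random.default_rng(seed)
    sags, truth, ref_sags = simulate_sag_set(cfg, rng=rng)
    ev = emit_evidence_tables(sags + ref_sags, truth, cfg, rng)
    keep = truth[truth["origin_class"] != "ssDNA_virus"]
    labels = pd.Series(
        (keep["origin_class"] == "dsDNA_phage").values,
        index=keep["contig_id"].values)
    if len(labels) > 2 * n_per_class:
        viral_ids = labels[labels].index[:n_per_class]
        nonviral_ids = labels[~labels].index[:n_per_class]
        labels = labels.loc[list(viral_ids) + list(nonviral_ids)]
    return clf.build_training_set(ev["orf_hits"], ev["recruitment"], labels)


_EVIDENCE_FILES = {
    "orf_hits": "orf_hits.tsv",
    "recruitment": "recruitment.tsv",
    "ssdna_hits": "ssdna_hits.tsv",
    "external_viral": "external_viral.tsv",
    "vog_lca": "vog_lca.tsv",
    "nt_verification": "nt_verification.tsv",
    "ref16s": "ref16s.tsv",
}


def _load_real_inputs(cfg: RunConfig):
    """Load a real-data input directory.

    Layout: ``fasta/*.fasta`` (headers ``>{sag_id}|{contig_id}``),
    ``taxonomy.tsv`` (sag_id, lineage, plastidic; lineage
    "bacterial_reference" marks the bacterial comparison SAGs), the
    evidence tables of :data:`_EVIDENCE_FILES` (optional ones may be
    absent), and optionally ``truth.tsv`` for planted-truth scoring.
    """
    from . import io as vio
    from .synthetic import SyntheticSAG

    root = Path(cfg.input_dir)
    tax_path = root / "taxonomy.tsv"
    if not tax_path.exists():
        raise FileNotFoundError(f"taxonomy file missing: {tax_path}")
    fasta_dir = root / "fasta"
    if not fasta_dir.is_dir():
        raise FileNotFoundError(f"FASTA directory missing: {fasta_dir}")
    taxa_df = vio.read_tsv(tax_path)
    for col in ("sag_id", "lineage", "plastidic"):
        if col not in taxa_df.columns:
            raise ValueError(f"{tax_path}: missing column {col!r}")
    lineage_of = dict(zip(taxa_df["sag_id"], taxa_df["lineage"]))
    plast_of = dict(zip(taxa_df["sag_id"], taxa_df["plastidic"]))
    sags, ref_sags = [], []
    for sag_id, contigs in vio.read_fasta_dir(fasta_dir):
        lineage = lineage_of.get(sag_id, "unidentified")
        s = SyntheticSAG(sag_id, lineage, bool(plast_of.get(sag_id, False)),
                         contigs)
        (ref_sags if lineage == "bacterial_reference" else sags).append(s)
    evidence = {}
    for key, fname in _EVIDENCE_FILES.items():
        p = root / fname
        if p.exists():
            evidence[key] = (vio.parse_hits_tsv(p) if key == "orf_hits"
                             else vio.read_tsv(p))
        elif key in ("orf_hits", "recruitment"):
            raise FileNotFoundError(f"required evidence table missing: {p}")
        else:
            evidence[key] = pd.DataFrame()
    truth = None
    if (root / "truth.tsv").exists():
        truth = vio.read_tsv(root / "truth.tsv")
    taxa_df = taxa_df[taxa_df["lineage"] != "bacterial_reference"]
    return sags, ref_sags, evidence, taxa_df, truth


def run_pipeline(cfg: RunConfig, training: clf.TrainingSet | None = None) -> dict:
    """Run all stages; returns the report dict (also written to
    ``out_dir/report.json`` together with stage TSVs)."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(message)s")

    sim = cfg.simulation
    if cfg.input_dir is None:
        rng = np.random.default_rng(sim.seed)
        log.info("simulate: generating SAG community")
        sags, truth, ref_sags = simulate_sag_set(sim, rng=rng)
        evidence = emit_evidence_tables(sags + ref_sags, truth, sim, rng)
        taxa_df = taxonomy_table(sags)
        if cfg.write_fasta:
            write_sag_fastas(sags + ref_sags, out / "fasta")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        taxa_df.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    else:
        log.info("load: reading real inputs from %s", cfg.input_dir)
        sags, ref_sags, evidence, taxa_df, truth = _load_real_inputs(cfg)

    log.info("sketch: %d protist + %d reference SAGs",
             len(sags), len(ref_sags))
    node_meta: dict[str, dict] = {}
    sketches = []
    lengths: dict[str, int] = {}
    for sag in sags + ref_sags:
        source = ("bacterial_reference" if sag.lineage == "bacterial_reference"
                  else "protist")
        for cid, seq in sag.contigs:
            node_meta[cid] = {"sag_id": sag.sag_id, "source": source}
            lengths[cid] = len(seq)
            sketches.append(sk.sketch(seq, cid, cfg.k, cfg.sketch_size,
                                      cfg.hash_seed))
    log.info("dist: all-vs-all Mash distances over %d contigs", len(sketches))
    records = sk.pairwise_distances(sketches, cfg.distance_threshold)
    pd.DataFrame([{"contig_a": r.contig_a, "contig_b": r.contig_b,
                   "jaccard": r.jaccard_estimate, "distance": r.mash_distance}
                  for r in records]).to_csv(out / "distances.tsv", sep="\t",
                                            index=False)

    log.info("classify: scoring %d protist contigs", sum(len(s.contigs) for s in sags))
    if training is None:
        training = make_training_set()
    ref_ids = {cid for sag in ref_sags for cid, _ in sag.contigs}
    ref16s_df = evidence.get("ref16s")
    ref16s = (set(ref16s_df["contig_id"])
              if ref16s_df is not None and "contig_id" in ref16s_df.columns
              else set())
    calls: dict[str, clf.ContigCall] = {}
    for sag in sags:
        for cid, _seq in sag.contigs:
            ev = clf.build_evidence(cid, lengths[cid], evidence, records,
                                    ref_ids, training, knn_k=cfg.knn_k,
                                    ssdna_max_len=sim.ssdna_length_max)
            calls[cid] = clf.classify_contig(ev, alpha=cfg.alpha)
    for cid in ref_ids:  # reference contigs are bacterial unless virally flagged
        calls[cid] = clf.ContigCall(cid, "bacterial", ("bacterial_reference_sag",))

    log.info("cluster: building network and communities")
    graph = net.build_contig_graph(records, node_meta, cfg.distance_threshold)
    clusters = net.detect_clusters(graph, seed=cfg.seed, method=cfg.clustering)
    categories = net.categorize_all(clusters, calls, ref16s, node_meta,
                                    cfg.viral_min_fraction)

    vog = evidence["vog_lca"]
    contig_lca: dict[str, str] = {}
    for cid, grp in vog.groupby("contig_id"):
        contig_lca[cid] = net.assign_contig_lca(
            list(zip(grp["orf_index"], grp["lca_label"])), cfg.lca_min_freq)
    for c in clusters:
        if c.category == "viral":
            net.cluster_lca(c, contig_lca)

    sag_contigs = {sag.sag_id: [cid for cid, _ in sag.contigs] for sag in sags}
    retained = net.filter_sags(sag_contigs, categories)
    sag_taxa = dict(zip(taxa_df["sag_id"], taxa_df["lineage"]))
    plastidic = dict(zip(taxa_df["sag_id"], taxa_df["plastidic"]))
    inter_table, edges = net.interphylum_clusters(clusters, sag_taxa)
    inter_ids = set(inter_table["cluster_id"])

    log.info("stats: summaries and association tests")
    summary = vstats.build_summary(retained, sag_contigs, categories, clusters,
                                   contig_lca, sag_taxa, plastidic, inter_ids,
                                   cfg.phage_lineages)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"cluster_id": c.cluster_id, "contig_id": m, "category": c.category,
          "lca_label": c.lca_label} for c in clusters for m in c.members]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    inter_table.to_csv(out / "interphylum.tsv", sep="\t", index=False)
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)

    tests = {}
    for col in ("has_virus", "has_bacteriophage", "has_interphylum_virus"):
        table = vstats.contingency_from_summary(summary, col)
        # rows whose TRUE or FALSE column is entirely absent break marginals
        table = table[(table.sum(axis=1) > 0)]
        entry = {"table": {t: [int(table.loc[t, "TRUE"]), int(table.loc[t, "FALSE"])]
                           for t in table.index}}
        try:
            stat, dof, p = vstats.chi_square_test(table.values)
            entry.update({"chi_square": stat, "dof": dof, "p_value": p})
        except ValueError as e:
            entry.update({"error": str(e)})
        tests[col] = entry

    counts_by_taxon = {t: g["n_viral_contigs"].to_numpy()
                       for t, g in summary.groupby("taxon")}
    anova_entry = {}
    if len(counts_by_taxon) >= 2:
        ftuple = vstats.one_way_anova(list(counts_by_taxon.values()))
        anova_entry = {"F": ftuple[0] if np.isfinite(ftuple[0]) else "inf",
                       "df_between": ftuple[1], "df_within": ftuple[2],
                       "p_value": ftuple[3]}
        try:
            _, letters = vstats.tukey_hsd(list(counts_by_taxon.values()),
                                          list(counts_by_taxon))
            anova_entry["tukey_letters"] = letters
        except ValueError:
            pass
    mw_entry = {}
    pl = summary[summary["plastidic"]]["n_viral_contigs"].to_numpy()
    apl = summary[~summary["plastidic"]]["n_viral_contigs"].to_numpy()
    if pl.size and apl.size:
        u, p = vstats.mann_whitney(apl, pl)
        mw_entry = {"U_aplastidic": u, "p_value": p,
                    "n_aplastidic": int(apl.size), "n_plastidic": int(pl.size)}

    prevalence = {
        t: float(g["has_virus"].mean()) for t, g in summary.groupby("taxon")}
    bounds = cs.cosort_bounds([sim.drop_volume],
                              (0.01, 0.1),
                              observed_prevalence=prevalence)

    report = {
        "tool": "virlink",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "n_sags": len(sags),
        "n_retained_sags": len(retained),
        "n_contigs": int(sum(len(s.contigs) for s in sags)),
        "n_clusters": len(clusters),
        "n_interphylum_clusters": int(len(inter_table)),
        "prevalence_by_lineage": prevalence,
        "contingency_tests": tests,
        "anova_viral_counts": anova_entry,
        "mann_whitney_aplastidic_vs_plastidic": mw_entry,
        "cosort_bounds": bounds,
    }
    report = _round6(_as_jsonable(report))
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("done in %.1fs", time.time() - t0)
    return {"report": report, "summary": summary, "truth": truth,
            "calls": calls, "clusters": clusters, "categories": categories,
            "interphylum": inter_table, "retained": retained,
            "sag_taxa": sag_taxa, "node_meta": node_meta}


def chi_square_power(n_runs: int = 200, n_sags_per_lineage: int = 50,
                     grazing_high: float = 3.0, concentration: float = 0.01,
                     drop_volume: float = 21.0, alpha: float = 0.01,
                     seed: int = 0) -> float:
    """Rejection rate of the virus-presence chi-square test under a
    two-high-grazing-lineage community.

    Four lineages at ``n_sags_per_lineage`` SAGs each; two graze viruses at
    ``grazing_high`` per cell, two not at all; every drop carries the
    co-sorting background at ``concentration * drop_volume``.  Each run
    simulates presence counts, tabulates has-virus by lineage, and tests
    independence; returns the fraction of runs with p < ``alpha``.
    """
    from .stats import chi_square_test
    from .synthetic import simulate_presence_counts

    lineages = ["HighA", "HighB", "LowA", "LowB"]
    rng = np.random.default_rng(seed)
    rejections = 0
    for run in range(n_runs):
        cfg = SimulationConfig(
            seed=int(rng.integers(2 ** 31)),
            n_sags_per_lineage={l: n_sags_per_lineage for l in lineages},
            lineage_grazing_rate={"HighA": grazing_high, "HighB": grazing_high,
                                  "LowA": 0.0, "LowB": 0.0},
            bacterial_prey_prob={l: 0.0 for l in lineages},
            virus_concentration=concentration, drop_volume=drop_volume,
            plastidic_lineages=())
        df = simulate_presence_counts(cfg)
        tab = df.assign(has=df["n_virus"] > 0).groupby("lineage")["has"] \
            .agg(["sum", "count"])
        cells = [[int(r["sum"]), int(r["count"] - r["sum"])]
                 for _, r in tab.iterrows()]
        try:
            _, _, p = chi_square_test(cells)
        except ValueError:  # a zero marginal: no rejection possible
            continue
        if p < alpha:
            rejections += 1
    return rejections / n_runs


ORIGIN_TO_CATEGORY = {"eukaryote": "eukaryote", "bacterium": "bacterial",
                      "dsDNA_phage": "viral", "ssDNA_virus": "viral"}


def evaluate_against_truth(result: dict) -> dict:
    """Score pipeline calls and inter-phylum recovery against planted truth.

    Returns per-class precision/recall/F1 (macro-averaged over the three
    call categories) for protist contigs, and precision/recall of the
    detected inter-phylum viral cluster set against the planted one
    (clusters compared as exact member-contig sets).
    """
    truth = result["truth"]
    calls = result["calls"]
    node_meta = result["node_meta"]
    prot = truth[truth["acquisition"] != "reference"]
    y_true, y_pred = [], []
    for _, row in prot.iterrows():
        cid = row["contig_id"]
        if cid not in calls:
            continue
        y_true.append(ORIGIN_TO_CATEGORY[row["origin_class"]])
        y_pred.append(calls[cid].category)
    per_class = {}
    for cat in ("viral", "bacterial", "eukaryote"):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cat and p == cat)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cat and p == cat)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cat and p != cat)
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 1.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cat] = {"precision": prec, "recall": rec, "f1": f1,
                          "support": tp + fn}
    macro_f1 = float(np.mean([v["f1"] for v in per_class.values()]))

    # planted inter-phylum clusters: virus cluster_ids spanning >=2 lineages
    sag_taxa = result["sag_taxa"]
    viral_truth = prot[prot["origin_class"].isin(["dsDNA_phage", "ssDNA_virus"])]
    planted = set()
    for cl_id, grp in viral_truth.groupby("cluster_id"):
        phyla = {sag_taxa.get(s, "unidentified") for s in grp["sag_id"]}
        phyla -= {"unidentified"}
        if len(phyla) >= 2:
            planted.add(frozenset(grp["contig_id"]))
    detected = set()
    by_id = {c.cluster_id: c for c in result["clusters"]}
    for cl_id in result["interphylum"]["cluster_id"]:
        members = [m for m in by_id[cl_id].members
                   if node_meta.get(m, {}).get("source") == "protist"]
        detected.add(frozenset(members))
    inter_tp = len(planted & detected)
    inter_prec = inter_tp / len(detected) if detected else 1.0
    inter_rec = inter_tp / len(planted) if planted else 1.0
    return {"per_class": per_class, "macro_f1": macro_f1,
            "interphylum_precision": inter_prec,
            "interphylum_recall": inter_rec,
            "n_planted_interphylum": len(planted),
            "n_detected_interphylum": len(detected),
            "n_contigs_scored": len(y_true)}
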