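"""Synthetic SAG community generator with planted ground truth.

Emulates the contig content of flow-sorted protistan single amplified
genomes (SAGs): each simulated cell carries host (eukaryote) contigs and,
depending on its lineage, bacterial prey fragments, grazed free viruses,
and viruses co-deposited in the sort drop.  Virus acquisition follows two
independent Poisson channels:

* grazing — mean ``lineage_grazing_rate[lineage]`` ingested viruses/cell,
* co-sorting — mean ``virus_concentration * drop_volume`` viruses/drop,
  the droplet co-encapsulation expectation (surface seawater carries
  ~1e7–1e8 viruses/mL, i.e. 0.01–0.1 viruses/pL; sort drops sample
  ~21–28 pL).

Each planted virus contig is a copy of a pool genome mutated at per-site
rate (1 - within_cluster_ani)/2, so two copies of the same virus planted in
different cells sit at ~within_cluster_ani pairwise identity and form a
near-identical (>95% ANI) cluster downstream.  Every emitted contig has
exactly one row in the planted-truth table recording its origin class
(eukaryote | bacterium | dsDNA_phage | ssDNA_virus), source genome and
acquisition channel, so recovery can be scored exactly.

The generator also fabricates the noisy evidence tables the classifier
consumes (ORF hit tables, read-recruitment counts, ssDNA alignment hits,
per-ORF LCA labels), with configurable per-channel false-positive and
false-negative rates.  Background genomes are i.i.d. uniform nucleotides:
downstream stages operate on k-mer identity and evidence tables, not gene
content.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "GenomePool",
    "SyntheticSAG",
    "generate_genome_pool",
    "mutate_to_ani",
    "simulate_sag_set",
    "simulate_presence_counts",
    "emit_evidence_tables",
    "write_sag_fastas",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: viral description terms used when fabricating nr ORF hits
VIRAL_HIT_TEMPLATES = [
    "major capsid protein",
    "phage terminase large subunit",
    "tail fiber protein",
    "portal protein [virus]",
    "baseplate assembly protein",
    "prophage integrase-associated virion protein",
]
NONVIRAL_HIT_TEMPLATES = [
    "hypothetical protein",
    "ABC transporter permease",
    "actin-related protein",
    "DNA polymerase family B",
    "ribosomal protein L3",
]

DSDNA_LINEAGES = ["Caudovirales"]
SSDNA_LINEAGES = ["Microviridae", "CRESS"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic SAG community.

    Defaults emulate a Gulf-of-Maine-like community: two suspension-feeding
    lineages with high virus ingestion (a choanoflagellate-like lineage at
    28 viruses/cell on average and a picozoan-like lineage at 5.7), the
    remaining lineages at low rates, and a co-sorting channel at the upper
    bound of typical surface seawater virus concentration (0.1 viruses/pL)
    times the 21 pL sample volume of a sort drop.
    """

    seed: int = 0
    n_sags_per_lineage: dict = field(default_factory=lambda: {
        "Choanozoa": 8, "Picozoa": 8, "Chlorophyta": 10,
        "Cercozoa": 10, "Stramenopiles": 12, "Alveolata": 12,
    })
    lineage_grazing_rate: dict = field(default_factory=lambda: {
        "Choanozoa": 28.0, "Picozoa": 5.7, "Chlorophyta": 1.0,
        "Cercozoa": 0.8, "Stramenopiles": 0.6, "Alveolata": 0.3,
    })
    bacterial_prey_prob: dict = field(default_factory=lambda: {
        "Choanozoa": 0.3, "Picozoa": 0.2, "Chlorophyta": 0.15,
        "Cercozoa": 0.3, "Stramenopiles": 0.2, "Alveolata": 0.1,
    })
    plastidic_lineages: tuple = ("Chlorophyta",)
    virus_concentration: float = 0.1  # viruses per pL
    drop_volume: float = 21.0  # pL
    n_virus_genomes: int = 40
    ssdna_fraction: float = 0.25  # fraction of virus pool that is ssDNA
    n_bacterial_genomes: int = 10
    n_euk_genomes: int = 20
    within_cluster_ani: float = 0.98
    euk_contig_length_range: tuple = (2000, 12000)
    euk_contigs_per_sag: tuple = (3, 7)
    bact_genome_length_range: tuple = (30000, 60000)
    bact_fragment_length_range: tuple = (5000, 15000)
    dsdna_genome_length_range: tuple = (15000, 60000)
    ssdna_genome_length_range: tuple = (3000, 8000)
    ssdna_length_max: int = 10000
    evidence_fp: float = 0.02  # per-channel false-positive rate
    evidence_fn: float = 0.05  # per-channel false-negative rate
    external_call_rate: float = 0.5  # fraction of dsDNA phage with a category-1/2 call

    def __post_init__(self) -> None:
        for name, rates in (("grazing rate", self.lineage_grazing_rate),):
            for lin, r in rates.items():
                if r < 0:
                    raise ValueError(f"negative {name} for {lin}")
        for lin, p in self.bacterial_prey_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"bacterial_prey_prob[{lin}] outside [0,1]")
        for lin in self.n_sags_per_lineage:
            if lin not in self.lineage_grazing_rate:
                raise ValueError(f"lineage {lin!r} missing from lineage_grazing_rate")
            if lin not in self.bacterial_prey_prob:
                raise ValueError(f"lineage {lin!r} missing from bacterial_prey_prob")
        if not 0.0 < self.within_cluster_ani <= 1.0:
            raise ValueError("within_cluster_ani must be in (0,1]")
        if self.virus_concentration < 0 or self.drop_volume <= 0:
            raise ValueError("virus_concentration >= 0 and drop_volume > 0 required")
        if not 0.0 <= self.evidence_fp <= 1.0 or not 0.0 <= self.evidence_fn <= 1.0:
            raise ValueError("evidence noise rates must be in [0,1]")
        for n in (self.n_virus_genomes, self.n_bacterial_genomes, self.n_euk_genomes):
            if n < 0:
                raise ValueError("genome counts must be non-negative")

    @classmethod
    def from_mapping(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("euk_contig_length_range", "euk_contigs_per_sag",
                    "bact_genome_length_range", "bact_fragment_length_range",
                    "dsdna_genome_length_range", "ssdna_genome_length_range",
                    "plastidic_lineages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class GenomeRecord:
    genome_id: str
    origin_class: str  # eukaryote | bacterium | dsDNA_phage | ssDNA_virus
    sequence: str
    lineage_label: str = ""  # viral taxonomic lineage for virus genomes


@dataclass
class GenomePool:
    eukaryote: list
    bacterium: list
    dsDNA_phage: list
    ssDNA_virus: list

    @property
    def viruses(self) -> list:
        return self.dsDNA_phage + self.ssDNA_virus


@dataclass
class SyntheticSAG:
    sag_id: str
    lineage: str
    plastidic: bool
    contigs: list  # list of (contig_id, sequence)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def generate_genome_pool(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenomePool:
    """Draw uniform-random source genomes per class; deterministic given seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for lo, hi in (config.euk_contig_length_range, config.bact_genome_length_range,
                   config.dsdna_genome_length_range, config.ssdna_genome_length_range):
        if lo <= 0 or hi < lo:
            raise ValueError("length ranges must be positive with low <= high")

    def draw(n, prefix, cls, length_range, lineages=None):
        out = []
        for i in range(n):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            lab = lineages[i % len(lineages)] if lineages else ""
            out.append(GenomeRecord(f"{prefix}{i:03d}", cls, _random_seq(rng, length), lab))
        return out

    n_ssdna = int(round(config.n_virus_genomes * config.ssdna_fraction))
    n_dsdna = config.n_virus_genomes - n_ssdna
    return GenomePool(
        eukaryote=draw(config.n_euk_genomes, "EUK", "eukaryote", config.euk_contig_length_range),
        bacterium=draw(config.n_bacterial_genomes, "BAC", "bacterium", config.bact_genome_length_range),
        dsDNA_phage=draw(n_dsdna, "PHG", "dsDNA_phage", config.dsdna_genome_length_range, DSDNA_LINEAGES),
        ssDNA_virus=draw(n_ssdna, "SSV", "ssDNA_virus", config.ssdna_genome_length_range, SSDNA_LINEAGES),
    )


def mutate_to_ani(sequence: str, target_ani: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability (1 - target_ani); substituted
    base always differs from the original; length preserved."""
    if not 0.0 < target_ani <= 1.0:
        raise ValueError(f"target_ani must be in (0,1], got {target_ani}")
    if not sequence:
        raise ValueError("cannot mutate an empty sequence")
    if target_ani == 1.0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype="S1").copy()
    hit = rng.random(arr.size) < (1.0 - target_ani)
    idx = np.flatnonzero(hit)
    if idx.size:
        codes = np.searchsorted(BASES, arr[idx])  # A,C,G,T -> 0..3
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def _poisson_counts(config: SimulationConfig, lineage: str, rng: np.random.Generator):
    grazed = int(rng.poisson(config.lineage_grazing_rate[lineage]))
    cosort = int(rng.poisson(config.virus_concentration * config.drop_volume))
    prey = bool(rng.random() < config.bacterial_prey_prob[lineage])
    return grazed, cosort, prey


def simulate_presence_counts(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Count-level simulation (no sequences): one row per SAG with the
    grazed/co-sorted virus counts and prey indicator.  Uses the same draws
    as :func:`simulate_sag_set`'s acquisition layer; suitable for power
    studies and Monte-Carlo checks of the co-sorting model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for lineage, n in config.n_sags_per_lineage.items():
        for i in range(n):
            grazed, cosort, prey = _poisson_counts(config, lineage, rng)
            rows.append({
                "sag_id": f"{lineage[:3].upper()}{i:04d}", "lineage": lineage,
                "n_grazed": grazed, "n_cosort": cosort,
                "n_virus": grazed + cosort, "has_prey": prey,
            })
    return pd.DataFrame(rows)


def simulate_sag_set(config: SimulationConfig, pool: GenomePool | None = None,
                     rng: np.random.Generator | None = None):
    """Simulate the full SAG set.

    Returns ``(sags, truth, ref_sags)`` where ``sags`` are protistan SAGs,
    ``truth`` the planted-truth DataFrame, and ``ref_sags`` bacterial
    reference SAGs (tiles of the bacterial pool genomes) used downstream
    as the bacterial comparison set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if pool is None:
        pool = generate_genome_pool(config, rng)
    needs_virus = any(r > 0 for r in config.lineage_grazing_rate.values()) or \
        config.virus_concentration * config.drop_volume > 0
    if needs_virus and not pool.viruses:
        raise ValueError("virus planting requested but virus pool is empty")
    if any(p > 0 for p in config.bacterial_prey_prob.values()) and not pool.bacterium:
        raise ValueError("bacterial prey requested but bacterial pool is empty")
    if not pool.eukaryote:
        raise ValueError("eukaryote genome pool is empty")

    copy_ani = 1.0 - (1.0 - config.within_cluster_ani) / 2.0
    sags: list[SyntheticSAG] = []
    truth_rows: list[dict] = []
    counter = 0

    def next_contig_id(sag_id: str) -> str:
        nonlocal counter
        counter += 1
        return f"{sag_id}_c{counter:05d}"

    def plant_virus(sag_id: str, contigs: list, acquisition: str) -> None:
        g = pool.viruses[int(rng.integers(len(pool.viruses)))]
        cid = next_contig_id(sag_id)
        contigs.append((cid, mutate_to_ani(g.sequence, copy_ani, rng)))
        truth_rows.append({
            "contig_id": cid, "sag_id": sag_id, "origin_class": g.origin_class,
            "source_genome_id": g.genome_id, "cluster_id": f"cl_{g.genome_id}",
            "acquisition": acquisition,
        })

    for lineage, n in sorted(config.n_sags_per_lineage.items()):
        for i in range(n):
            sag_id = f"{lineage[:3].upper()}{i:04d}"
            contigs: list = []
            host = pool.eukaryote[int(rng.integers(len(pool.eukaryote)))]
            n_host = int(rng.integers(config.euk_contigs_per_sag[0],
                                      config.euk_contigs_per_sag[1] + 1))
            for _ in range(max(1, n_host)):
                lo, hi = config.euk_contig_length_range
                length = int(rng.integers(lo, min(hi, len(host.sequence)) + 1))
                start = int(rng.integers(0, len(host.sequence) - length + 1))
                frag = mutate_to_ani(host.sequence[start:start + length], copy_ani, rng)
                cid = next_contig_id(sag_id)
                contigs.append((cid, frag))
                truth_rows.append({
                    "contig_id": cid, "sag_id": sag_id, "origin_class": "eukaryote",
                    "source_genome_id": host.genome_id,
                    "cluster_id": f"cl_{host.genome_id}", "acquisition": "host",
                })
            grazed, cosort, prey = _poisson_counts(config, lineage, rng)
            if prey and pool.bacterium:
                g = pool.bacterium[int(rng.integers(len(pool.bacterium)))]
                lo, hi = config.bact_fragment_length_range
                length = int(rng.integers(lo, min(hi, len(g.sequence)) + 1))
                start = int(rng.integers(0, len(g.sequence) - length + 1))
                cid = next_contig_id(sag_id)
                contigs.append((cid, mutate_to_ani(g.sequence[start:start + length], copy_ani, rng)))
                truth_rows.append({
                    "contig_id": cid, "sag_id": sag_id, "origin_class": "bacterium",
                    "source_genome_id": g.genome_id,
                    "cluster_id": f"cl_{g.genome_id}", "acquisition": "prey",
                })
            for _ in range(grazed):
                plant_virus(sag_id, contigs, "grazed_virus")
            for _ in range(cosort):
                plant_virus(sag_id, contigs, "cosort")
            sags.append(SyntheticSAG(sag_id, lineage,
                                     lineage in config.plastidic_lineages, contigs))

    # bacterial reference SAGs: one per pool genome, tiled into contigs
    ref_sags: list[SyntheticSAG] = []
    tile = max(config.bact_fragment_length_range[0], 5000)
    for g in pool.bacterium:
        sag_id = f"BREF_{g.genome_id}"
        contigs = []
        for start in range(0, len(g.sequence), tile):
            piece = g.sequence[start:start + tile]
            if len(piece) < 1000:
                continue
            cid = next_contig_id(sag_id)
            contigs.append((cid, piece))
            truth_rows.append({
                "contig_id": cid, "sag_id": sag_id, "origin_class": "bacterium",
                "source_genome_id": g.genome_id, "cluster_id": f"cl_{g.genome_id}",
                "acquisition": "reference",
            })
        ref_sags.append(SyntheticSAG(sag_id, "bacterial_reference", False, contigs))

    truth = pd.DataFrame(truth_rows, columns=[
        "contig_id", "sag_id", "origin_class", "source_genome_id",
        "cluster_id", "acquisition"])
    return sags, truth, ref_sags


def _n_orfs(length: int) -> int:
    # fixed grid: one ORF per 900 bp, at least one per contig
    return max(1, length // 900)


def emit_evidence_tables(sags, truth: pd.DataFrame, config: SimulationConfig,
                         rng: np.random.Generator):
    """Fabricate the evidence tables consumed by the classifier.

    Returns a dict of DataFrames: ``orf_hits``, ``recruitment``,
    ``ssdna_hits``, ``external_viral``, ``vog_lca``, ``nt_verification``,
    ``ref16s`` — the in-silico counterparts of the homology-search outputs
    the real pipeline would read.
    """
    truth_by_contig = truth.set_index("contig_id")
    fp, fn = config.evidence_fp, config.evidence_fn
    orf_rows, rec_rows, ssdna_rows, ext_rows, vog_rows, nt_rows = [], [], [], [], [], []
    ref16s = []

    # mark one tile per reference genome as carrying a 16S gene
    seen_ref_genome = set()
    for sag in sags:
        for cid, seq in sag.contigs:
            if cid not in truth_by_contig.index:
                raise KeyError(f"contig {cid} missing from truth table")
            row = truth_by_contig.loc[cid]
            cls = row["origin_class"]
            length = len(seq)
            n_orf = _n_orfs(length)
            is_ref = row["acquisition"] == "reference"
            if is_ref and row["source_genome_id"] not in seen_ref_genome:
                ref16s.append(cid)
                seen_ref_genome.add(row["source_genome_id"])

            viral_class = cls in ("dsDNA_phage", "ssDNA_virus")
            genome_lineage = ""
            if viral_class:
                # lineage recorded in genome id prefix convention
                genome_lineage = "Caudovirales" if cls == "dsDNA_phage" else (
                    "Microviridae" if int(row["source_genome_id"][3:]) % 2 == 0 else "CRESS")

            for o in range(n_orf):
                hit_viral = (rng.random() < (1 - fn)) if cls == "dsDNA_phage" \
                    else (rng.random() < fp)
                templates = VIRAL_HIT_TEMPLATES if hit_viral else NONVIRAL_HIT_TEMPLATES
                rank_of_viral = int(rng.integers(1, 11)) if hit_viral else 0
                for rank in range(1, 4):
                    if hit_viral and rank == min(rank_of_viral, 3):
                        desc = templates[int(rng.integers(len(VIRAL_HIT_TEMPLATES)))]
                    else:
                        desc = NONVIRAL_HIT_TEMPLATES[int(rng.integers(len(NONVIRAL_HIT_TEMPLATES)))]
                    orf_rows.append({
                        "qseqid": cid, "orf_index": o, "rank": rank, "stitle": desc,
                        "pident": float(np.round(rng.uniform(40, 95), 1)),
                        "alignment_fraction": float(np.round(rng.uniform(0.5, 1.0), 3)),
                        "subject_class": "nr",
                    })
                # RefSeq-bacteria channel
                bact_hit = (rng.random() < (1 - fn)) if cls == "bacterium" \
                    else (rng.random() < fp)
                if bact_hit:
                    orf_rows.append({
                        "qseqid": cid, "orf_index": o, "rank": 1,
                        "stitle": "bacterial conserved protein",
                        "pident": float(np.round(rng.uniform(55, 95), 1)),
                        "alignment_fraction": float(np.round(rng.uniform(0.8, 1.0), 3)),
                        "subject_class": "refseq_bacteria",
                    })
                if viral_class:
                    lab = genome_lineage if rng.random() < (1 - fn) else "none"
                    vog_rows.append({"contig_id": cid, "orf_index": o, "lca_label": lab})

            # recruitment: viral contigs recruit predominantly from the virome
            viral_like = viral_class
            if viral_class and rng.random() < fn:
                viral_like = False
            elif not viral_class and rng.random() < fp:
                viral_like = True
            base_v = length / 100.0 if viral_like else length / 1000.0
            base_b = length / 1000.0 if viral_like else length / 100.0
            rec_rows.append({
                "contig_id": cid,
                "viral_reads": int(rng.poisson(base_v)),
                "bacterial_reads": int(rng.poisson(base_b)),
                "viral_metagenome_size": 1_000_000,
                "bacterial_metagenome_size": 1_000_000,
                "contig_length": length,
            })

            # ssDNA tBLASTx-like hits
            ssdna_hit = (cls == "ssDNA_virus" and rng.random() < (1 - fn)) or \
                (cls != "ssDNA_virus" and rng.random() < fp)
            if ssdna_hit:
                span = int(0.4 * length) if cls == "ssDNA_virus" else int(0.25 * length)
                ssdna_rows.append({
                    "contig_id": cid, "subject_id": "ssdna_db_ref",
                    "evalue": 1e-20, "aligned_start": 0, "aligned_end": span,
                })

            # external viral-category calls (VirSorter-like), dsDNA phage only
            if cls == "dsDNA_phage" and rng.random() < config.external_call_rate * (1 - fn):
                ext_rows.append({"contig_id": cid, "category": int(rng.integers(1, 3))})
            elif cls == "eukaryote" and rng.random() < fp * config.external_call_rate:
                ext_rows.append({"contig_id": cid, "category": int(rng.integers(1, 4))})

            # nt verification for contigs with bacterial ORF evidence
            if cls == "bacterium":
                nt_rows.append({"contig_id": cid,
                                "verification": "bacterial" if rng.random() < (1 - fn) else "unknown"})

    missing = set(truth_by_contig.index) - {c for sag in sags for c, _ in sag.contigs}
    if missing:
        raise KeyError(f"truth rows without emitted contigs: {sorted(missing)[:3]}")

    return {
        "orf_hits": pd.DataFrame(orf_rows, columns=[
            "qseqid", "orf_index", "rank", "stitle", "pident",
            "alignment_fraction", "subject_class"]),
        "recruitment": pd.DataFrame(rec_rows, columns=[
            "contig_id", "viral_reads", "bacterial_reads",
            "viral_metagenome_size", "bacterial_metagenome_size", "contig_length"]),
        "ssdna_hits": pd.DataFrame(ssdna_rows, columns=[
            "contig_id", "subject_id", "evalue", "aligned_start", "aligned_end"]),
        "external_viral": pd.DataFrame(ext_rows, columns=["contig_id", "category"]),
        "vog_lca": pd.DataFrame(vog_rows, columns=["contig_id", "orf_index", "lca_label"]),
        "nt_verification": pd.DataFrame(nt_rows, columns=["contig_id", "verification"]),
        "ref16s": pd.DataFrame({"contig_id": ref16s}),
    }


def write_sag_fastas(sags, out_dir) -> list[Path]:
    """One FASTA per SAG, 80-column wrapped, headers ``>{sag_id}|{contig_id}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sag in sags:
        p = out_dir / f"{sag.sag_id}.fasta"
        with open(p, "w") as fh:
            for cid, seq in sag.contigs:
                fh.write(f">{sag.sag_id}|{cid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths.append(p)
    return paths


def taxonomy_table(sags) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sag_id": s.sag_id, "lineage": s.lineage, "plastidic": s.plastidic}
         for s in sags], columns=["sag_id", "lineage", "plastidic"])
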