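"""Per-contig evidence scoring and viral/bacterial/eukaryote calls.

The viral screen combines three signals, mirroring a ViruSCope-style
workflow:

1. **Viral-ORF fraction** — the fraction of a contig's ORFs whose top-N nr
   hits contain a virus-associated term (whole-word, case-insensitive
   match against a fixed lexicon).
2. **Recruitment ratio** — log10 of the per-million-scaled, pseudocounted
   ratio of reads recruited from a viral versus a bacterial metagenome at
   >=50% identity; positive values indicate virome enrichment.
3. **kNN score** — the two features, z-scored against a labelled training
   set, are classified by k-nearest neighbours; the score is the fraction
   of viral neighbours, with an exact binomial tail p-value against the
   training base rate.

Supplementary rules: a contig is flagged as an ssDNA virus when it is
shorter than 10 kb and qualifying alignments to ssDNA virus genomes
(e < 1e-5) cover at least 20% of its length; contigs in external
viral-screen categories 1 or 2 are accepted as viral.  Bacterial calls
come from Mash matches to bacterial reference contigs (d <= 0.05) or from
a strict majority of ORFs hitting RefSeq bacterial proteins (>50% identity
over >75% of the ORF) confirmed by nucleotide-level verification.
Anything else is assumed eukaryotic.  When rules conflict, precedence is
viral > bacterial > eukaryote; the ``basis`` field keeps every fired rule
for audit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "VIRAL_LEXICON",
    "TrainingSet",
    "ContigEvidence",
    "ContigCall",
    "viral_orf_fraction",
    "recruitment_ratio",
    "knn_viral_score",
    "ssdna_flag",
    "bacterial_by_reference",
    "bacterial_by_orf_majority",
    "classify_contig",
    "build_evidence",
    "build_training_set",
]

# virus-associated description terms ("tail" appears once; the source list
# repeats it)
VIRAL_LEXICON = (
    "phage", "virus", "prophage", "terminase", "t4-like", "lambda-like",
    "mu-like", "capsid", "tail", "fiber", "lambdoid", "portal", "virion",
    "lysis", "podovirus", "podo-like", "head", "baseplate", "myovirus",
    "siphovirus", "structural",
)

MISSING = float("nan")


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def _term_matcher(lexicon=VIRAL_LEXICON):
    """Whole-word, case-insensitive matcher with plural folding: a
    description token matches a lexicon term if it equals the term or the
    term plus an 's'/'es' plural suffix (so "viruses" counts for "virus",
    but "viroid" does not)."""
    terms = {t.lower() for t in lexicon}
    expanded = terms | {t + "s" for t in terms} | {t + "es" for t in terms}

    def matches(description: str) -> bool:
        return any(tok in expanded for tok in _TOKEN_RE.findall(description.lower()))

    return matches


_DEFAULT_MATCHER = _term_matcher()


@dataclass
class TrainingSet:
    """Labelled (viral_orf_fraction, recruitment_ratio) points with the
    standardisation constants derived from them."""

    features: np.ndarray  # (n, 2)
    labels: np.ndarray  # bool, True = viral
    means: np.ndarray = field(init=False)
    sds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.features.ndim != 2 or self.features.shape[1] != 2:
            raise ValueError("training features must be (n, 2)")
        if np.isnan(self.features).any():
            raise ValueError("training features contain missing values")
        if self.labels.all() or not self.labels.any():
            raise ValueError("training set must contain both labels")
        self.means = self.features.mean(axis=0)
        self.sds = self.features.std(axis=0, ddof=0)
        if np.any(self.sds == 0):
            raise ValueError("zero variance in a training feature")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def base_rate(self) -> float:
        return float(self.labels.mean())


@dataclass
class ContigEvidence:
    contig_id: str
    viral_orf_fraction: float = MISSING
    recruitment_ratio: float = MISSING
    knn_probability: float = MISSING
    knn_pvalue: float = MISSING
    external_viral_category: int | None = None  # 1, 2, 3 or None
    ssdna_flag: bool = False
    bacterial_by_reference: bool = False
    bacterial_by_orf_majority: bool = False
    nt_verification: str = "unknown"  # bacterial | organellar | unknown


@dataclass(frozen=True)
class ContigCall:
    contig_id: str
    category: str  # viral | bacterial | eukaryote
    basis: tuple = ()


def viral_orf_fraction(hits: pd.DataFrame, contig_id: str,
                       lexicon=VIRAL_LEXICON, top_n: int = 10) -> float:
    """Fraction of a contig's ORFs with a virus-term hit in the top ``top_n``
    nr hits.  Returns NaN (missing) when the contig has no nr-class ORF hits."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    match = _DEFAULT_MATCHER if lexicon is VIRAL_LEXICON else _term_matcher(lexicon)
    sub = hits[(hits["qseqid"] == contig_id) & (hits["subject_class"] == "nr")]
    if sub.empty:
        return MISSING
    sub = sub[sub["rank"] <= top_n]
    by_orf = sub.groupby("orf_index")["stitle"].apply(
        lambda titles: any(match(t) for t in titles))
    n_orfs = sub["orf_index"].nunique()
    return float(by_orf.sum() / n_orfs)


def recruitment_ratio(viral_reads: int, bacterial_reads: int,
                      viral_metagenome_size: int, bacterial_metagenome_size: int) -> float:
    """log10 of the pseudocounted reads-per-million ratio, virome over
    bacterial metagenome."""
    if viral_metagenome_size <= 0 or bacterial_metagenome_size <= 0:
        raise ValueError("metagenome sizes must be positive")
    v = (viral_reads + 1) / (viral_metagenome_size / 1e6)
    b = (bacterial_reads + 1) / (bacterial_metagenome_size / 1e6)
    return math.log10(v / b)


def knn_viral_score(point, training: TrainingSet, k: int = 5):
    """k-nearest-neighbour viral probability and binomial-tail p-value.

    Features are z-scored by the training means/SDs; Euclidean metric.
    Ties at the k-th distance include all tied points (probability
    renormalised over the points actually used).  The p-value is the exact
    binomial tail P(X >= observed viral neighbours) under the training-set
    viral base rate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(training):
        raise ValueError(f"k={k} exceeds training size {len(training)}")
    q = (np.asarray(point, dtype=float) - training.means) / training.sds
    z = (training.features - training.means) / training.sds
    d = np.sqrt(((z - q) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")
    kth = d[order[k - 1]]
    used = order[d[order] <= kth]  # all points tied at the k-th distance
    n_used = len(used)
    n_viral = int(training.labels[used].sum())
    prob = n_viral / n_used
    p = float(sstats.binom.sf(n_viral - 1, n_used, training.base_rate))
    return prob, min(p, 1.0)


def _merge_spans(spans):
    merged = []
    for lo, hi in sorted(spans):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def ssdna_flag(hits, contig_length: int, max_len: int = 10000,
               evalue_max: float = 1e-5, min_cover: float = 0.2) -> bool:
    """ssDNA-virus rule: contig shorter than ``max_len`` with qualifying
    hits (e-value < ``evalue_max``) whose merged spans cover at least
    ``min_cover`` of the contig."""
    spans = []
    for h in hits:
        lo, hi = h["aligned_start"], h["aligned_end"]
        if lo < 0 or hi < lo or hi > contig_length:
            raise ValueError(f"invalid aligned span ({lo},{hi}) on length {contig_length}")
        if h["evalue"] < evalue_max:
            spans.append((lo, hi))
    if contig_length >= max_len:
        return False
    covered = sum(hi - lo for lo, hi in _merge_spans(spans))
    return covered >= min_cover * contig_length


def bacterial_by_reference(records, bacterial_ref_ids: set, contig_id: str,
                           threshold: float = 0.05) -> bool:
    """True iff the contig matches a bacterial reference contig at Mash
    distance <= threshold (inclusive)."""
    for r in records:
        if r.mash_distance > threshold:
            continue
        other = None
        if r.contig_a == contig_id:
            other = r.contig_b
        elif r.contig_b == contig_id:
            other = r.contig_a
        if other is not None and other in bacterial_ref_ids:
            return True
    return False


def bacterial_by_orf_majority(hits: pd.DataFrame, contig_id: str,
                              nt_verification: str,
                              min_identity: float = 50.0,
                              min_fraction: float = 0.75) -> bool:
    """True iff a strict majority (>50%) of the contig's ORFs hit a RefSeq
    bacterial protein above the identity/coverage thresholds AND the
    nucleotide-level verification supports a bacterial (not organellar)
    origin."""
    sub = hits[hits["qseqid"] == contig_id]
    if sub.empty:
        return False
    n_orfs = sub["orf_index"].nunique()
    bact = sub[(sub["subject_class"] == "refseq_bacteria")
               & (sub["pident"] > min_identity)
               & (sub["alignment_fraction"] > min_fraction)]
    n_qual = bact["orf_index"].nunique()
    return (n_qual > 0.5 * n_orfs) and nt_verification == "bacterial"


def classify_contig(ev: ContigEvidence, p_thresh: float = 0.5,
                    alpha: float = 0.05) -> ContigCall:
    """Combine all evidence into a single category call.

    Viral if the kNN score clears both the probability threshold and the
    p-value gate, or an external viral-screen category-1/2 call exists, or
    the ssDNA rule fires; else bacterial if either bacterial rule fires;
    else eukaryote.  ``basis`` records every rule that fired regardless of
    the final category.
    """
    basis = []
    knn_ok = (not math.isnan(ev.knn_probability)
              and not math.isnan(ev.knn_pvalue)
              and ev.knn_probability > p_thresh and ev.knn_pvalue <= alpha)
    if knn_ok:
        basis.append("knn")
    if ev.external_viral_category in (1, 2):
        basis.append("external_viral_category")
    if ev.ssdna_flag:
        basis.append("ssdna")
    if ev.bacterial_by_reference:
        basis.append("bacterial_by_reference")
    if ev.bacterial_by_orf_majority:
        basis.append("bacterial_by_orf_majority")
    if knn_ok or ev.external_viral_category in (1, 2) or ev.ssdna_flag:
        category = "viral"
    elif ev.bacterial_by_reference or ev.bacterial_by_orf_majority:
        category = "bacterial"
    else:
        category = "eukaryote"
    return ContigCall(ev.contig_id, category, tuple(basis))


def build_evidence(contig_id: str, contig_length: int, evidence_tables: dict,
                   distance_records, bacterial_ref_ids: set,
                   training: TrainingSet | None, knn_k: int = 5,
                   top_n: int = 10, ssdna_max_len: int = 10000) -> ContigEvidence:
    """Assemble a ContigEvidence bundle for one contig from the raw tables."""
    orf = evidence_tables["orf_hits"]
    rec = evidence_tables["recruitment"]
    ev = ContigEvidence(contig_id)
    ev.viral_orf_fraction = viral_orf_fraction(orf, contig_id, top_n=top_n)
    row = rec[rec["contig_id"] == contig_id]
    if not row.empty:
        r = row.iloc[0]
        ev.recruitment_ratio = recruitment_ratio(
            int(r["viral_reads"]), int(r["bacterial_reads"]),
            int(r["viral_metagenome_size"]), int(r["bacterial_metagenome_size"]))
    if training is not None and not math.isnan(ev.viral_orf_fraction) \
            and not math.isnan(ev.recruitment_ratio):
        ev.knn_probability, ev.knn_pvalue = knn_viral_score(
            (ev.viral_orf_fraction, ev.recruitment_ratio), training, k=knn_k)
    ext = evidence_tables.get("external_viral")
    if ext is not None and not ext.empty:
        m = ext[ext["contig_id"] == contig_id]
        if not m.empty:
            ev.external_viral_category = int(m.iloc[0]["category"])
    ss = evidence_tables.get("ssdna_hits")
    if ss is not None and not ss.empty:
        hits = ss[ss["contig_id"] == contig_id].to_dict("records")
        ev.ssdna_flag = ssdna_flag(hits, contig_length, max_len=ssdna_max_len)
    nt = evidence_tables.get("nt_verification")
    if nt is not None and not nt.empty:
        m = nt[nt["contig_id"] == contig_id]
        if not m.empty:
            ev.nt_verification = str(m.iloc[0]["verification"])
    ev.bacterial_by_reference = bacterial_by_reference(
        distance_records, bacterial_ref_ids, contig_id)
    ev.bacterial_by_orf_majority = bacterial_by_orf_majority(
        orf, contig_id, ev.nt_verification)
    return ev


def build_training_set(orf_hits: pd.DataFrame, recruitment: pd.DataFrame,
                       labels: pd.Series, top_n: int = 10) -> TrainingSet:
    """Build a training set from evidence tables and viral/nonviral labels
    (index = contig_id).  Contigs with missing features are dropped."""
    feats, labs = [], []
    rec_by_id = recruitment.set_index("contig_id")
    for cid, lab in labels.items():
        if cid not in rec_by_id.index:
            continue
        f = viral_orf_fraction(orf_hits, cid, top_n=top_n)
        if math.isnan(f):
            continue
        r = rec_by_id.loc[cid]
        ratio = recruitment_ratio(int(r["viral_reads"]), int(r["bacterial_reads"]),
                                  int(r["viral_metagenome_size"]),
                                  int(r["bacterial_metagenome_size"]))
        feats.append((f, ratio))
        labs.append(bool(lab))
    return TrainingSet(np.array(feats), np.array(labs))
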