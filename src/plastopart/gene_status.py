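"""Intact / pseudogene / lost / uncertain classification of plastid genes.

A gene's *presence* is measured against a reference panel by sequence, not
by annotation: the coverage of the reference CDS by matches found in the
genome (both strands). A gene is

* **lost** when under 30% of the reference is present (strict ``<``),
* **pseudogene** when present but its conceptual translation carries an
  internal stop codon, lacks a terminal stop, or its length departs from
  the reference by a non-multiple of three (a frameshift),
* **uncertain** when N runs inside the region prevent a call (degraded
  assemblies with scaffolded contigs),
* **intact** otherwise.

A missing or non-canonical start codon is recorded as evidence but does
not by itself demote a gene. RNA editing is not modelled: a missing stop
is a pseudogene call even where C-to-U editing might restore it in vivo;
this caveat travels with the evidence records.

Coverage mechanics: maximal exact matches (>= 30 bp) between the reference
CDS and the genome are collected first; where a matched region is only
patchily covered (a diverged copy rather than a clean truncation), the
locus is re-scored by Smith-Waterman local alignment (match +1, mismatch
-1, gap open -2, extend -1) and accepted at identity >= 0.7 over >= 30
aligned bases. Coverage is the fraction of reference positions covered by
the union of accepted matches.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .core_io import (
    GeneFeature,
    PlastomeRecord,
    START_CODONS,
    extract_feature_sequence,
    feature_genome_position,
    reverse_complement,
    translate_cds,
)

__all__ = [
    "Finding",
    "GeneStatus",
    "ReferencePanel",
    "build_reference_panel",
    "assess_presence",
    "classify_gene",
    "status_matrix",
]

_STOPS = {"TAA", "TAG", "TGA"}
LOST_THRESHOLD = 0.30  # strict: lost iff coverage < 0.30
MIN_EXACT_MATCH = 30
MIN_ALIGN_LEN = 30
MIN_ALIGN_IDENTITY = 0.7
_SEED_K = 16


@dataclass(frozen=True)
class Finding:
    kind: str  # internal_stop | missing_stop | missing_start | frameshift |
    #            coverage_fraction | contains_N | noncanonical_start
    position: int | None = None  # genome position where applicable
    value: float | None = None
    note: str | None = None


@dataclass
class GeneStatus:
    gene: str
    sample: str
    status: str  # intact | pseudogene | lost | uncertain
    evidence: list[Finding]
    copy_count: int

    def has(self, kind: str) -> bool:
        return any(f.kind == kind for f in self.evidence)


@dataclass
class ReferencePanel:
    """Per-gene reference CDS, the modal intact copy across a set of records."""

    genes: dict[str, tuple[int, str]]  # name -> (length, exemplar sequence)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def length(self, gene: str) -> int:
        return self.genes[gene][0]

    def sequence(self, gene: str) -> str:
        return self.genes[gene][1]

    def names(self) -> list[str]:
        return sorted(self.genes)


def _looks_intact(seq: str) -> bool:
    if len(seq) < 9 or len(seq) % 3 or "N" in seq:
        return False
    if seq[:3] not in START_CODONS or seq[-3:] not in _STOPS:
        return False
    return "*" not in translate_cds(seq)[:-1]


def build_reference_panel(records: list[PlastomeRecord]) -> ReferencePanel:
    """Pick, per gene, the most common intact CDS length (ties -> longest)
    and one exemplar sequence of that length."""
    by_gene: dict[str, list[str]] = {}
    seen: set[str] = set()
    for rec in records:
        done_here: set[str] = set()
        for f in rec.features:
            if f.kind != "CDS" or f.name in done_here:
                continue
            done_here.add(f.name)
            seen.add(f.name)
            seq = extract_feature_sequence(rec, f)
            if not f.pseudo_flag and _looks_intact(seq):
                by_gene.setdefault(f.name, []).append(seq)
    for name in sorted(seen - set(by_gene)):
        warnings.warn(f"gene {name}: no intact copy in any record; omitted from panel")
    genes = {}
    for name, seqs in by_gene.items():
        counts = Counter(len(s) for s in seqs)
        best_len = max(counts, key=lambda L: (counts[L], L))
        exemplar = next(s for s in seqs if len(s) == best_len)
        genes[name] = (best_len, exemplar)
    return ReferencePanel(genes)


# ---------------------------------------------------------------------------
# presence by sequence


def _genome_index(record: PlastomeRecord) -> dict[str, list[int]]:
    idx = getattr(record, "_kmer_index", None)
    if idx is None:
        idx = {}
        g = record.seq
        for i in range(len(g) - _SEED_K + 1):
            idx.setdefault(g[i : i + _SEED_K], []).append(i)
        record._kmer_index = idx  # cached per record instance
    return idx


def _exact_matches(query: str, record: PlastomeRecord) -> list[tuple[int, int, int, str]]:
    """Maximal exact matches of query against both genome strands.

    Returns (q0, g0, length, strand) with 0-based starts; for '-' strand
    the genome start refers to the plus-strand coordinates of the matched
    block (whose reverse complement equals the query block).
    """
    idx = _genome_index(record)
    g = record.seq
    n = len(g)
    out = []
    for strand in ("+", "-"):
        q = query if strand == "+" else reverse_complement(query)
        covered: dict[int, int] = {}  # diagonal -> q end already explained
        for i in range(0, len(q) - _SEED_K + 1):
            kmer = q[i : i + _SEED_K]
            if "N" in kmer:
                continue
            for gpos in idx.get(kmer, ()):
                d = gpos - i
                if covered.get(d, -1) >= i:
                    continue
                s_q, s_g = i, gpos
                while s_q > 0 and s_g > 0 and q[s_q - 1] == g[s_g - 1] != "N":
                    s_q -= 1
                    s_g -= 1
                e_q, e_g = i + _SEED_K, gpos + _SEED_K
                while e_q < len(q) and e_g < n and q[e_q] == g[e_g] != "N":
                    e_q += 1
                    e_g += 1
                covered[d] = e_q
                L = e_q - s_q
                if strand == "+":
                    out.append((s_q, s_g, L, strand))
                else:
                    out.append((len(query) - e_q, s_g, L, strand))
    return out


_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


def _cluster(matches, max_diag_gap=40, max_pos_gap=150):
    """Group matches into candidate loci by strand/diagonal proximity.

    Along one locus the conserved quantity is g0 - q0 on the plus strand
    but g0 + q0 on the minus strand (reference coordinates run backwards).
    """
    def diag(m):
        q0, g0, _L, strand = m
        return g0 - q0 if strand == "+" else g0 + q0

    clusters: list[list] = []
    for m in sorted(matches, key=lambda m: (m[3], m[1])):
        q0, g0, L, strand = m
        placed = False
        for cl in clusters:
            _cq0, cg0, cL, cstrand = cl[-1]
            if (
                cstrand == strand
                and abs(diag(m) - diag(cl[-1])) <= max_diag_gap
                and g0 - (cg0 + cL) <= max_pos_gap
            ):
                cl.append(m)
                placed = True
                break
        if not placed:
            clusters.append([m])
    return clusters


def assess_presence(
    ref_cds: str, record: PlastomeRecord
) -> tuple[float, list[dict]]:
    """Coverage of a reference CDS by the genome, plus the matched loci."""
    if len(ref_cds) < 30:
        raise ValueError("reference CDS must be at least 30 bp")
    matches = _exact_matches(ref_cds, record)
    covered: set[int] = set()
    for q0, g0, L, strand in matches:
        if L >= MIN_EXACT_MATCH:
            covered.update(range(q0, q0 + L))
    loci = []
    for cl in _cluster(matches):
        q_lo = min(m[0] for m in cl)
        q_hi = max(m[0] + m[2] for m in cl)
        g_lo = min(m[1] for m in cl)
        g_hi = max(m[1] + m[2] for m in cl)
        strand = cl[0][3]
        exact_in_span = sum(m[2] for m in cl)
        if q_hi - q_lo >= MIN_ALIGN_LEN and exact_in_span < 0.95 * (q_hi - q_lo):
            # patchy locus: likely a diverged copy; re-score by local alignment
            w_lo = max(0, g_lo - 60)
            w_hi = min(record.length, g_hi + 60)
            window = record.seq[w_lo:w_hi]
            query = ref_cds if strand == "+" else reverse_complement(ref_cds)
            alns = _aligner.align(window, query)
            if len(alns):
                aln = alns[0]
                t_blocks, q_blocks = aln.aligned
                cols = matched = 0
                for (t0, t1), (s0, s1) in zip(t_blocks, q_blocks):
                    cols += t1 - t0
                    matched += sum(
                        1
                        for a, b in zip(window[t0:t1], str(aln.query)[s0:s1])
                        if a == b != "N"
                    )
                if cols >= MIN_ALIGN_LEN and matched / cols >= MIN_ALIGN_IDENTITY:
                    for (s0, s1) in q_blocks:
                        if strand == "+":
                            covered.update(range(s0, s1))
                        else:
                            covered.update(
                                range(len(ref_cds) - s1, len(ref_cds) - s0)
                            )
        frac = len({p for m in cl for p in range(m[0], m[0] + m[2])}) / len(ref_cds)
        loci.append(
            {
                "interval": (g_lo + 1, g_hi),
                "strand": strand,
                "ref_span": (q_lo + 1, q_hi),
                "ref_fraction": round(frac, 4),
            }
        )
    coverage = len(covered) / len(ref_cds)
    return coverage, loci


# ---------------------------------------------------------------------------
# classification


def _cds_findings(
    seq: str,
    ref_len: int,
    codon_start: int,
    record: PlastomeRecord | None = None,
    feature: GeneFeature | None = None,
) -> list[Finding]:
    findings: list[Finding] = []
    s = seq[codon_start - 1 :]
    s = s[: len(s) - len(s) % 3]
    aa = translate_cds(seq, codon_start)
    if "*" in aa[:-1]:
        i_aa = aa[:-1].index("*")
        pos = None
        if record is not None and feature is not None:
            pos = feature_genome_position(
                record, feature, codon_start - 1 + 3 * i_aa
            )
        findings.append(Finding("internal_stop", position=pos, value=float(i_aa)))
    if not s or s[-3:] not in _STOPS:
        findings.append(Finding("missing_stop"))
    if (len(seq) - ref_len) % 3 != 0:
        findings.append(
            Finding("frameshift", value=float((len(seq) - ref_len) % 3))
        )
    start = seq[:3]
    if start not in START_CODONS:
        findings.append(Finding("missing_start"))
    elif start == "GTG":
        findings.append(Finding("noncanonical_start", note="GTG start"))
    if "N" in seq:
        findings.append(Finding("contains_N"))
    return findings


def classify_gene(
    gene: str, record: PlastomeRecord, panel: ReferencePanel
) -> GeneStatus:
    """Classify one gene in one sample against the reference panel."""
    if gene not in panel:
        raise KeyError(f"gene {gene} is not in the reference panel")
    ref = panel.sequence(gene)
    coverage, loci = assess_presence(ref, record)
    evidence = [Finding("coverage_fraction", value=round(coverage, 4))]
    annotated = [f for f in record.features if f.name == gene and f.kind == "CDS"]
    copy_count = len(annotated) if annotated else sum(
        1 for l in loci if l["ref_fraction"] >= 0.5
    )
    if coverage < LOST_THRESHOLD:
        return GeneStatus(gene, record.id, "lost", evidence, copy_count)
    if annotated:
        primary = max(annotated, key=lambda f: f.spliced_length(record.length))
        seq = extract_feature_sequence(record, primary)
        evidence += _cds_findings(
            seq, panel.length(gene), primary.codon_start, record, primary
        )
    elif loci:
        best = max(loci, key=lambda l: l["ref_fraction"])
        a, b = best["interval"]
        region = record.seq[a - 1 : b]
        if best["strand"] == "-":
            region = reverse_complement(region)
        # translate in the reference frame at the locus's starting offset
        r0 = best["ref_span"][0] - 1
        frame_trim = (3 - r0 % 3) % 3
        evidence += _cds_findings(region[frame_trim:], panel.length(gene), 1)
    bad = {"internal_stop", "missing_stop", "frameshift"}
    if any(f.kind in bad for f in evidence):
        status = "pseudogene"
    elif any(f.kind == "contains_N" for f in evidence):
        status = "uncertain"
    else:
        status = "intact"
    return GeneStatus(gene, record.id, status, evidence, copy_count)


def status_matrix(
    records: list[PlastomeRecord], panel: ReferencePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-by-sample status matrix plus per-sample summary counts.

    IR-duplicated genes are counted once in the "unique" tallies; the
    intact total counts every annotated copy.
    """
    rows = []
    for rec in records:
        for gene in panel.names():
            st = classify_gene(gene, rec, panel)
            rows.append(
                {
                    "sample": rec.id,
                    "gene": gene,
                    "status": st.status,
                    "copy_count": st.copy_count,
                    "evidence": ";".join(
                        f.kind + (f"@{f.position}" if f.position else "")
                        for f in st.evidence
                        if f.kind != "coverage_fraction"
                    ),
                    "coverage": next(
                        f.value for f in st.evidence if f.kind == "coverage_fraction"
                    ),
                }
            )
    matrix = pd.DataFrame(rows)
    counts = []
    for rec in records:
        sub = matrix[matrix["sample"] == rec.id]
        intact = sub[sub.status == "intact"]
        counts.append(
            {
                "sample": rec.id,
                "intact_total": int(intact.copy_count.sum()),
                "intact_unique": len(intact),
                "pseudogene": int((sub.status == "pseudogene").sum()),
                "lost": int((sub.status == "lost").sum()),
                "uncertain": int((sub.status == "uncertain").sum()),
            }
        )
    return matrix, pd.DataFrame(counts)
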