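"""Comparative reporting: per-sample summary rows, shared-CDS extraction
and plain-text junction diagrams."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .core_io import PlastomeRecord, extract_feature_sequence, gc_content
from .gene_status import ReferencePanel, build_reference_panel, classify_gene, status_matrix
from .junction_typing import classify_jsa
from .quadripartite import QuadripartiteMap, canonicalize, detect_quadripartite, junction_profiles
from .repeats import scan_tandem_repeats

__all__ = [
    "ComparativeRow",
    "COLUMNS",
    "summarize",
    "compare",
    "extract_shared_cds",
    "junction_diagram",
]

#: Frozen column order of the comparative table.
COLUMNS = [
    "sample",
    "total_len",
    "lsc_len",
    "ssc_len",
    "ir_len",
    "gc_percent",
    "tandem_count",
    "tandem_total_bp",
    "tandem_percent",
    "intact_total",
    "intact_unique",
    "pseudogene",
    "lost",
    "uncertain",
    "trna_total",
    "trna_unique",
    "rrna_total",
    "rrna_unique",
    "jsa_type",
    "ycf1_bp_in_ira",
]


@dataclass
class ComparativeRow:
    sample: str
    total_len: int
    lsc_len: int | None
    ssc_len: int | None
    ir_len: int | None
    gc_percent: float
    tandem_count: int
    tandem_total_bp: int
    tandem_percent: float
    intact_total: int | None
    intact_unique: int | None
    pseudogene: int | None
    lost: int | None
    uncertain: int | None
    trna_total: int | None
    trna_unique: int | None
    rrna_total: int | None
    rrna_unique: int | None
    jsa_type: str | None
    ycf1_bp_in_ira: int | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in COLUMNS}


def _rna_counts(record: PlastomeRecord, kind: str) -> tuple[int, int]:
    feats = [f for f in record.features if f.kind == kind]
    return len(feats), len({f.name for f in feats})


def summarize(
    record: PlastomeRecord,
    panel: ReferencePanel | None = None,
    min_ir_len: int = 1000,
    ab_threshold: int = 2000,
) -> ComparativeRow:
    """One comparative-table row for a single plastome.

    Partition failure yields a row with the no-IR fields empty while
    length, GC and tandem statistics are still computed. Records without
    annotations get sequence-level statistics only.
    """
    qmap = detect_quadripartite(record, min_ir_len) if record.circular else None
    _, tsum = scan_tandem_repeats(record)
    has_genes = any(f.kind == "CDS" for f in record.features)
    intact_total = intact_unique = pseudo = lost = uncertain = None
    if has_genes:
        if panel is None:
            panel = build_reference_panel([record])
        _, counts = status_matrix([record], panel)
        row = counts.iloc[0]
        intact_total = int(row.intact_total)
        intact_unique = int(row.intact_unique)
        pseudo = int(row.pseudogene)
        lost = int(row.lost)
        uncertain = int(row.uncertain)
    trna_t, trna_u = _rna_counts(record, "tRNA") if record.features else (None, None)
    rrna_t, rrna_u = _rna_counts(record, "rRNA") if record.features else (None, None)
    jsa_label = ycf1_bp = None
    if qmap is not None and has_genes:
        jsa = classify_jsa(None, qmap, record, ab_threshold)
        jsa_label = jsa.type
        ycf1_bp = jsa.ycf1_bp_in_ira
    return ComparativeRow(
        sample=record.id,
        total_len=record.length,
        lsc_len=qmap.lsc_len if qmap else None,
        ssc_len=qmap.ssc_len if qmap else None,
        ir_len=qmap.ir_len if qmap else None,
        gc_percent=gc_content(record.seq),
        tandem_count=tsum["count"],
        tandem_total_bp=tsum["total_bp"],
        tandem_percent=tsum["percent_of_genome"],
        intact_total=intact_total,
        intact_unique=intact_unique,
        pseudogene=pseudo,
        lost=lost,
        uncertain=uncertain,
        trna_total=trna_t,
        trna_unique=trna_u,
        rrna_total=rrna_t,
        rrna_unique=rrna_u,
        jsa_type=jsa_label,
        ycf1_bp_in_ira=ycf1_bp,
    )


def compare(
    records: list[PlastomeRecord],
    panel: ReferencePanel | None = None,
    min_ir_len: int = 1000,
    ab_threshold: int = 2000,
) -> pd.DataFrame:
    """Comparative table across samples (one row each, frozen columns)."""
    if panel is None and any(f.kind == "CDS" for r in records for f in r.features):
        panel = build_reference_panel(records)
    rows = [summarize(r, panel, min_ir_len, ab_threshold).to_dict() for r in records]
    return pd.DataFrame(rows, columns=COLUMNS)


def extract_shared_cds(
    records: list[PlastomeRecord], panel: ReferencePanel | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Per-gene unaligned CDS sets for genes intact in every sample.

    A gene enters the shared set only when classified intact everywhere
    (pseudogenes, losses and uncertain N-containing copies all exclude it);
    IR-duplicated genes contribute one sequence per sample.
    """
    if len(records) < 2:
        raise ValueError("shared-CDS extraction needs at least two records")
    if panel is None:
        panel = build_reference_panel(records)
    shared: dict[str, list[tuple[str, str]]] = {}
    for gene in panel.names():
        entries = []
        ok = True
        for rec in records:
            st = classify_gene(gene, rec, panel)
            if st.status != "intact":
                ok = False
                break
            feats = [f for f in rec.features if f.name == gene and f.kind == "CDS"]
            primary = max(feats, key=lambda f: f.spliced_length(rec.length))
            entries.append((rec.id, extract_feature_sequence(rec, primary)))
        if ok:
            shared[gene] = entries
    return shared


def junction_diagram(record: PlastomeRecord, qmap: QuadripartiteMap) -> str:
    """Fixed-format text rendering of the J_SB and J_SA structures."""
    rec, m = canonicalize(record, qmap)
    profiles = {p.junction: p for p in junction_profiles(m, rec)}
    pseudo_names = {f.name for f in rec.features if f.pseudo_flag}

    def mark(name: str) -> str:
        return ("ψ" + name) if name in pseudo_names else name

    lines = []
    for junc, left, right in (("J_SB", "IRb", "SSC"), ("J_SA", "SSC", "IRa")):
        p = profiles[junc]
        pos = m.junctions[junc]
        lines.append(f"{junc}  {left} | {right}   position {pos:,}")
        if p.overlapping_gene is None:
            lines.append("      no junction-spanning gene")
        else:
            ir_name = "IRb" if junc == "J_SB" else "IRa"
            sc_name = "SSC"
            lines.append(
                f"      {mark(p.overlapping_gene)}: {p.bp_in_sc:,} bp in {sc_name}"
                f" / {p.bp_in_ir:,} bp in {ir_name}"
            )
        if p.genes_fully_in_ir_adjacent:
            inner = ", ".join(mark(g) for g in p.genes_fully_in_ir_adjacent[:6])
            lines.append(f"      nearest genes inside the IR: {inner}")
    return "\n".join(lines) + "\n"
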