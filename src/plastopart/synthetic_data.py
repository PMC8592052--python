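"""Synthetic annotated plastomes with machine-readable truth tables.

Generates a circular genome with the canonical quadripartite layout
(LSC + IRb + SSC + IRa, IRb an exact reverse complement of IRa), a
reduced-scale but realistically ordered gene inventory (a junction-spanning
*ycf1*, the *ndh* suite in the SSC and LSC, rRNA/tRNA blocks duplicated in
the IRs), planted gene-degradation lesions (internal stops, frameshifts,
truncations, missing stops, N patches, whole-gene deletions), planted
dispersed repeat pairs and perfect tandem arrays — plus a truth table
recording the realised coordinates and expected calls for every planted
element, so each downstream analysis can be verified by construct-and-
recover with no external data.

The default genome is ~42 kb (20 kb LSC, 7.2 kb IRs, 7.6 kb SSC), roughly
a quarter of a real plastome, so whole-pipeline checks over many seeds run
in seconds. Output is deterministic for a given seed.

Structural history can be simulated on top: :func:`apply_ir_expansion`
moves the SSC/IRa junction into the SSC by a chosen extent, duplicating the
incorporated segment into IRb (the long double-strand-break copy-repair
mechanism, or the short gene-conversion mechanism for extents <= 200 bp),
and :func:`delete_region` models gene loss, enabling multi-event
reconstructions of derived junction types from an ancestral genome.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import (
    GeneFeature,
    Interval,
    PlastomeRecord,
    reverse_complement,
)
from .quadripartite import QuadripartiteMap, canonical_map

__all__ = [
    "GeneDef",
    "SynthSpec",
    "TruthTable",
    "build_plastome",
    "apply_ir_expansion",
    "delete_region",
    "default_inventory",
]

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")
MIN_SPACER = 20


@dataclass(frozen=True)
class GeneDef:
    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str
    exons: tuple[int, ...]  # spliced exon lengths, transcription order
    introns: tuple[int, ...] = ()

    @property
    def spliced(self) -> int:
        return sum(self.exons)


def default_inventory() -> dict[str, list[GeneDef]]:
    """Reduced-scale gene inventory in genomic order per compartment.

    SSC genes run from the J_SB side towards J_SA; IR genes are listed for
    IRa from the J_SA side towards J_LA (IRb mirrors them automatically).
    Lengths are scaled-down but relative placement follows the typical
    angiosperm plastome.
    """
    lsc = [
        GeneDef("psbA", "CDS", "-", (600,)),
        GeneDef("trnK", "tRNA", "-", (72,)),
        GeneDef("matK", "CDS", "-", (900,)),
        GeneDef("atpA", "CDS", "-", (780,)),
        GeneDef("rps2", "CDS", "+", (711,)),
        GeneDef("rbcL", "CDS", "+", (720,)),
        GeneDef("cemA", "CDS", "+", (690,)),
        GeneDef("ndhC", "CDS", "-", (363,)),
        GeneDef("ndhK", "CDS", "-", (501,)),
        GeneDef("ndhJ", "CDS", "-", (477,)),
        GeneDef("trnQ", "tRNA", "-", (72,)),
        GeneDef("clpP", "CDS", "-", (591,)),
    ]
    ssc = [
        GeneDef("ndhF", "CDS", "-", (555,)),
        GeneDef("rpl32", "CDS", "+", (171,)),
        GeneDef("ccsA", "CDS", "+", (387,)),
        GeneDef("ndhD", "CDS", "-", (453,)),
        GeneDef("psaC", "CDS", "-", (246,)),
        GeneDef("ndhE", "CDS", "-", (306,)),
        GeneDef("ndhG", "CDS", "-", (531,)),
        GeneDef("ndhI", "CDS", "-", (504,)),
        GeneDef("ndhA", "CDS", "-", (273, 270), (210,)),
        GeneDef("ndhH", "CDS", "-", (591,)),
        GeneDef("rps15", "CDS", "+", (273,)),
    ]
    ira = [
        GeneDef("trnN", "tRNA", "-", (72,)),
        GeneDef("rrn5", "rRNA", "+", (116,)),
        GeneDef("rrn4.5", "rRNA", "+", (95,)),
        GeneDef("rrn23", "rRNA", "+", (1500,)),
        GeneDef("trnA", "tRNA", "+", (88,)),
        GeneDef("trnI", "tRNA", "+", (74,)),
        GeneDef("rrn16", "rRNA", "+", (900,)),
        GeneDef("trnV", "tRNA", "-", (72,)),
        GeneDef("rps7", "CDS", "-", (468,)),
        GeneDef("ndhB", "CDS", "-", (768,)),
        GeneDef("rpl2", "CDS", "-", (825,)),
        GeneDef("rpl23", "CDS", "-", (282,)),
    ]
    return {"lsc": lsc, "ssc": ssc, "ira": ira}


@dataclass
class PlantedRepeat:
    direction: str  # forward | inverted
    length: int
    mismatches: int
    region1: str = "lsc"
    region2: str = "lsc"
    near1: int | None = None  # preferred absolute genome position
    near2: int | None = None


@dataclass
class PlantedTandem:
    unit_len: int
    copies: int
    region: str = "lsc"


@dataclass
class SynthSpec:
    """Blueprint for one synthetic plastome."""

    seed: int
    lsc_len: int = 20000
    ir_len: int = 7200
    ssc_len: int = 7600
    jsa_type: str = "A"
    ycf1_len: int = 2400
    ycf1_bp_in_ira: int = 1000  # ignored for Type C (full containment)
    ndhh_trunc_frac: float = 0.5  # Type C only: retained ndhH fraction
    gc_target: float = 0.38
    planted_status: dict[str, tuple] = field(default_factory=dict)
    planted_dispersed: list[PlantedRepeat] = field(default_factory=list)
    planted_tandem: list[PlantedTandem] = field(default_factory=list)
    pinned_spacers: dict[str, int] = field(default_factory=dict)
    jsa_spacer: int | None = None  # SSC spacer just before ycf1's tail

    @classmethod
    def type_a(cls, seed: int, **kw) -> "SynthSpec":
        return cls(seed=seed, jsa_type="A", ycf1_bp_in_ira=1000, **kw)

    @classmethod
    def type_b(cls, seed: int, **kw) -> "SynthSpec":
        kw.setdefault("ir_len", 8900)
        kw.setdefault("ssc_len", 6200)
        kw.setdefault("ycf1_len", 3600)
        return cls(seed=seed, jsa_type="B", ycf1_bp_in_ira=2700, **kw)

    @classmethod
    def type_c(cls, seed: int, **kw) -> "SynthSpec":
        kw.setdefault("ir_len", 10400)
        kw.setdefault("ssc_len", 4400)
        return cls(seed=seed, jsa_type="C", **kw)


@dataclass
class TruthTable:
    """Realised coordinates and expected calls for every planted element."""

    lsc_len: int
    ir_len: int
    ssc_len: int
    genome_len: int
    jsa_type: str
    ycf1_bp_in_ira: int
    extra_ir_genes: list[str]
    statuses: dict[str, str]
    lesions: dict[str, tuple]
    copy_counts: dict[str, int]
    gene_lengths: dict[str, int]  # pre-lesion reference CDS lengths
    repeats: list[dict]
    tandems: list[dict]
    spacers: dict[str, list[Interval]]  # free background intervals per region

    def expected_map(self) -> QuadripartiteMap:
        return canonical_map(self.lsc_len, self.ir_len, self.ssc_len)


# ---------------------------------------------------------------------------
# sequence helpers


def _bg(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _codon_weights(gc: float) -> np.ndarray:
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in _CODONS])
    return w / w.sum()


def _random_cds(rng: np.random.Generator, length: int, gc: float = 0.38) -> str:
    """Random sense codons at the genome's base composition, ATG..stop."""
    assert length % 3 == 0 and length >= 9
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_CODONS, size=n_codons, p=_codon_weights(gc)))
    return "ATG" + body + _STOPS[rng.integers(len(_STOPS))]


def _primitive(unit: str) -> bool:
    p = len(unit)
    return not any(p % d == 0 and unit == unit[:d] * (p // d) for d in range(1, p))


# ---------------------------------------------------------------------------
# lesions


def _apply_lesion(
    cds: str, lesion: tuple, rng: np.random.Generator
) -> tuple[str, str, dict]:
    """Apply one lesion to a CDS string.

    Returns (mutated sequence, expected status, detail dict).
    """
    kind = lesion[0]
    L = len(cds)
    if kind == "internal_stop":
        i = L // 6 * 3  # codon-aligned, in the first half
        mutated = cds[:i] + "TAA" + cds[i + 3 :]
        return mutated, "pseudogene", {"cds_offset": i}
    if kind == "frameshift":
        i = L // 2
        mutated = cds[:i] + cds[i + 1 :]
        return mutated, "pseudogene", {"cds_offset": i}
    if kind == "missing_stop":
        mutated = cds[:-3] + "GGA"
        return mutated, "pseudogene", {}
    if kind == "missing_start":
        mutated = "ATC" + cds[3:]
        return mutated, "intact", {}
    if kind == "truncate":
        frac = float(lesion[1])
        keep = max(9, int(round(L * frac)))
        realized = keep / L
        status = "lost" if realized < 0.30 else "pseudogene"
        return cds[:keep], status, {"realized_fraction": realized}
    if kind == "n_patch":
        i = L // 2 // 3 * 3
        width = 6
        mutated = cds[:i] + "N" * width + cds[i + width :]
        return mutated, "uncertain", {"cds_offset": i}
    if kind == "delete":
        return "", "lost", {}
    raise ValueError(f"unknown lesion kind {kind!r}")


def _enforce_exact_ir_bounds(
    seq: list[str],
    lsc_len: int,
    ir_len: int,
    ssc_len: int,
    features: Sequence[GeneFeature],
) -> None:
    """Pin the detected IR to the designed boundaries.

    A maximal exact inverted repeat extends by one base whenever the
    single-copy flanks happen to be complementary (probability ~1/4 per
    junction in random background). Break both extension conditions by
    adjusting one non-genic flank base, so construct-and-recover is exact.
    """
    L = len(seq)
    genic: set[int] = set()
    for f in features:
        for e in f.exons:
            if e.wraps:
                genic.update(range(e.start - 1, L))
                genic.update(range(0, e.end))
            else:
                genic.update(range(e.start - 1, e.end))

    def comp(b: str) -> str:
        return {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[b]

    def break_pair(p: int, q: int) -> None:
        # ensure seq[p] != comp(seq[q]); tweak whichever flank is background
        if seq[p] != comp(seq[q]):
            return
        for pos, other in ((p, q), (q, p)):
            if pos not in genic:
                seq[pos] = next(
                    b for b in "ACGT" if b != comp(seq[other]) and b != seq[pos]
                )
                return
        raise ValueError("cannot pin IR boundary: both flanks are genic")

    # outer flanks: LSC's last base pairs with LSC's first base (via J_LA wrap)
    break_pair(lsc_len - 1, 0)
    # inner flanks: SSC's first base pairs with SSC's last base
    break_pair(lsc_len + ir_len, lsc_len + ir_len + ssc_len - 1)


# ---------------------------------------------------------------------------
# layout


@dataclass
class _Part:
    text: str
    gene: GeneDef | None = None
    pseudo: bool = False
    pinned_after: int | None = None  # fixed spacer width after this part


def _gene_part(
    gd: GeneDef,
    seqs: dict[str, str],
    rng_bg: np.random.Generator,
    gc: float,
) -> _Part:
    """Genomic (plus-strand) text of a gene, introns included."""
    spliced = seqs[gd.name]
    pieces = []
    off = 0
    for ex in gd.exons:
        take = min(ex, max(0, len(spliced) - off))
        pieces.append(spliced[off : off + take])
        off += take
    if gd.strand == "+":
        texts = pieces
        introns = [_bg(rng_bg, w, gc) for w in gd.introns]
        body = texts[0]
        for t, i in zip(texts[1:], introns):
            body += i + t
    else:
        texts = [reverse_complement(p) for p in pieces][::-1]
        introns = [_bg(rng_bg, w, gc) for w in gd.introns][::-1]
        body = texts[0]
        for t, i in zip(texts[1:], introns):
            body += i + t
    return _Part(text=body, gene=gd)


def _layout(
    parts: list[_Part],
    target_len: int,
    rng: np.random.Generator,
    gc: float,
    head_pinned: bool = False,
    tail_pinned: bool = False,
) -> tuple[str, list[tuple[_Part, int]], list[tuple[int, int]]]:
    """Assemble parts with random spacers to an exact target length.

    Returns (compartment string, [(part, 0-based offset)], spacer spans).
    ``head_pinned``/``tail_pinned`` suppress the leading/trailing spacer so
    a part can sit flush against the compartment boundary.
    """
    content = sum(len(p.text) for p in parts)
    gaps = len(parts) + 1 - int(head_pinned) - int(tail_pinned)
    fixed = {}
    for idx, p in enumerate(parts[:-1]):
        if p.pinned_after is not None:
            fixed[idx] = p.pinned_after
    remaining = target_len - content - sum(fixed.values())
    free_gaps = gaps - len(fixed)
    if remaining < MIN_SPACER * free_gaps or remaining < 0:
        raise ValueError(
            f"infeasible packing: {content} bp of content + spacers "
            f"exceed the {target_len} bp compartment"
        )
    widths = []
    gap_slots = []  # gap i sits before part i (i == len(parts) -> tail gap)
    for i in range(len(parts) + 1):
        if i == 0 and head_pinned:
            widths.append(0)
        elif i == len(parts) and tail_pinned:
            widths.append(0)
        elif i >= 1 and (i - 1) in fixed:
            widths.append(fixed[i - 1])
        else:
            widths.append(None)
            gap_slots.append(i)
    base = remaining // max(1, free_gaps)
    extra = remaining - base * free_gaps
    free_widths = [base] * free_gaps
    for j in rng.choice(free_gaps, size=extra, replace=True) if extra else []:
        free_widths[j] += 1
    for slot, w in zip(gap_slots, free_widths):
        widths[slot] = w
    out = []
    placed = []
    spacers = []
    pos = 0
    for i, p in enumerate(parts):
        w = widths[i]
        if w:
            out.append(_bg(rng, w, gc))
            spacers.append((pos, pos + w - 1))
            pos += w
        out.append(p.text)
        placed.append((p, pos))
        pos += len(p.text)
    w = widths[len(parts)]
    if w:
        out.append(_bg(rng, w, gc))
        spacers.append((pos, pos + w - 1))
        pos += w
    assert pos == target_len
    return "".join(out), placed, spacers


def _feature_for(
    gd: GeneDef, abs_start0: int, pseudo: bool, realized_len: int
) -> GeneFeature:
    """Build the annotation for a gene part laid out at ``abs_start0``."""
    if len(gd.exons) == 1:
        iv = Interval(abs_start0 + 1, abs_start0 + realized_len)
        return GeneFeature(gd.name, gd.kind, gd.strand, [iv], pseudo_flag=pseudo)
    # multi-exon (transcription-order exon list; minus strand laid out as
    # revcomp(last exon) .. intron .. revcomp(first exon))
    assert gd.strand == "-" and len(gd.exons) == 2 and realized_len == gd.spliced
    e1, e2 = gd.exons
    (intron,) = gd.introns
    ex2 = Interval(abs_start0 + 1, abs_start0 + e2)
    ex1 = Interval(abs_start0 + e2 + intron + 1, abs_start0 + e2 + intron + e1)
    return GeneFeature(gd.name, gd.kind, gd.strand, [ex1, ex2], pseudo_flag=pseudo)


# ---------------------------------------------------------------------------
# main builder


def build_plastome(spec: SynthSpec) -> tuple[PlastomeRecord, TruthTable]:
    """Assemble a synthetic plastome and its truth table from a spec."""
    rng_genes = np.random.default_rng([spec.seed, 17])
    rng_layout = np.random.default_rng([spec.seed, 31])
    rng_plant = np.random.default_rng([spec.seed, 53])
    inv = default_inventory()
    gc = spec.gc_target

    if spec.jsa_type not in ("A", "B", "C"):
        raise ValueError(f"jsa_type must be A, B or C, got {spec.jsa_type!r}")

    # gene sequences are drawn from their own stream in a fixed order, so
    # two specs with the same seed share gene content regardless of lesions
    all_defs = inv["lsc"] + inv["ssc"] + inv["ira"] + [
        GeneDef("ycf1", "CDS", "-", (spec.ycf1_len,))
    ]
    seqs: dict[str, str] = {}
    for gd in all_defs:
        if gd.kind == "CDS":
            seqs[gd.name] = _random_cds(rng_genes, gd.spliced, gc)
        else:
            seqs[gd.name] = _bg(rng_genes, gd.spliced, gc)

    gene_lengths = {g.name: g.spliced for g in all_defs if g.kind == "CDS"}

    prelesion = dict(seqs)  # full-length CDS before any lesion
    statuses: dict[str, str] = {}
    lesions: dict[str, tuple] = {}
    lesion_details: dict[str, dict] = {}
    deleted: set[str] = set()
    for gd in all_defs:
        if gd.name in spec.planted_status:
            lesion = spec.planted_status[gd.name]
            if len(gd.exons) > 1 and lesion[0] != "delete":
                raise ValueError(f"lesions on multi-exon genes unsupported ({gd.name})")
            if gd.name == "ycf1" or (spec.jsa_type == "C" and gd.name in ("ndhH", "rps15")):
                raise ValueError(f"cannot lesion junction-structural gene {gd.name}")
            mutated, status, detail = _apply_lesion(seqs[gd.name], lesion, rng_genes)
            seqs[gd.name] = mutated
            statuses[gd.name] = status
            lesions[gd.name] = lesion
            lesion_details[gd.name] = detail
            if status == "lost" and lesion[0] == "delete":
                deleted.add(gd.name)
        elif gd.kind == "CDS":
            statuses[gd.name] = "intact"

    # Type C structural arrangement: ycf1 wholly in IRa, preceded (from the
    # J_SA side) by rps15 and a truncated, stop-less ndhH pseudogene.
    ssc_defs = [g for g in inv["ssc"] if g.name not in deleted]
    ira_defs = list(inv["ira"])
    extra_ir_genes: list[str] = []
    if spec.jsa_type == "C":
        ssc_defs = [g for g in ssc_defs if g.name not in ("ndhH", "rps15")]
        keep = max(9, int(round(gene_lengths["ndhH"] * spec.ndhh_trunc_frac)))
        seqs["ndhH"] = seqs["ndhH"][:keep]
        statuses["ndhH"] = "pseudogene"
        lesions["ndhH"] = ("truncate", spec.ndhh_trunc_frac)
        lesion_details["ndhH"] = {"realized_fraction": keep / gene_lengths["ndhH"]}
        extra_ir_genes = ["ndhH", "rps15"]
    lsc_defs = [g for g in inv["lsc"] if g.name not in deleted]

    # --- compartment part lists -------------------------------------------
    def parts_for(defs: Sequence[GeneDef]) -> list[_Part]:
        out = []
        for gd in defs:
            p = _gene_part(gd, seqs, rng_layout, gc)
            p.pseudo = statuses.get(gd.name) not in (None, "intact")
            if gd.name in spec.pinned_spacers:
                p.pinned_after = spec.pinned_spacers[gd.name]
            out.append(p)
        return out

    lsc_parts = parts_for(lsc_defs)
    ycf1_text = reverse_complement(seqs["ycf1"])  # minus strand, 5' at high coords

    if spec.jsa_type in ("A", "B"):
        bp_ira = spec.ycf1_bp_in_ira
        if not 0 < bp_ira < spec.ycf1_len:
            raise ValueError("ycf1_bp_in_ira must split the gene across J_SA")
        tail = _Part(text=ycf1_text[: spec.ycf1_len - bp_ira], gene=None)
        head = _Part(text=ycf1_text[spec.ycf1_len - bp_ira :], gene=None)
        ssc_parts = parts_for(ssc_defs)
        if spec.jsa_spacer is not None:
            ssc_parts[-1].pinned_after = spec.jsa_spacer
        ssc_parts.append(tail)
        ira_parts = [head] + parts_for(ira_defs)
        ssc_str, ssc_placed, ssc_spc = _layout(
            ssc_parts, spec.ssc_len, rng_layout, gc, tail_pinned=True
        )
        ira_str, ira_placed, ira_spc = _layout(
            ira_parts, spec.ir_len, rng_layout, gc, head_pinned=True
        )
    else:  # Type C
        ndhh_part = _gene_part(
            GeneDef("ndhH", "CDS", "-", (len(seqs["ndhH"]),)), seqs, rng_layout, gc
        )
        ndhh_part.pseudo = True
        rps15_part = _gene_part(
            GeneDef("rps15", "CDS", "+", (gene_lengths["rps15"],)), seqs, rng_layout, gc
        )
        ycf1_part = _Part(text=ycf1_text, gene=GeneDef("ycf1", "CDS", "-", (spec.ycf1_len,)))
        ssc_parts = parts_for(ssc_defs)
        ira_parts = [ndhh_part, rps15_part, ycf1_part] + parts_for(ira_defs)
        ssc_str, ssc_placed, ssc_spc = _layout(ssc_parts, spec.ssc_len, rng_layout, gc)
        ira_str, ira_placed, ira_spc = _layout(ira_parts, spec.ir_len, rng_layout, gc)
        ndhh_part.gene = GeneDef("ndhH", "CDS", "-", (len(seqs["ndhH"]),))
        rps15_part.gene = GeneDef("rps15", "CDS", "+", (gene_lengths["rps15"],))

    lsc_str, lsc_placed, lsc_spc = _layout(lsc_parts, spec.lsc_len, rng_layout, gc)
    irb_str = reverse_complement(ira_str)

    L_total = spec.lsc_len + 2 * spec.ir_len + spec.ssc_len
    off_lsc = 0
    off_irb = spec.lsc_len
    off_ssc = spec.lsc_len + spec.ir_len
    off_ira = spec.lsc_len + spec.ir_len + spec.ssc_len

    features: list[GeneFeature] = []
    copy_counts: dict[str, int] = {}

    def add_placed(placed, offset):
        for part, local0 in placed:
            if part.gene is None:
                continue
            f = _feature_for(part.gene, offset + local0, part.pseudo, len(part.text) if len(part.gene.exons) == 1 else part.gene.spliced)
            features.append(f)
            copy_counts[part.gene.name] = copy_counts.get(part.gene.name, 0) + 1

    add_placed(lsc_placed, off_lsc)
    add_placed(ssc_placed, off_ssc)
    add_placed(ira_placed, off_ira)

    # IRb mirrors of everything annotated fully inside IRa
    for part, local0 in ira_placed:
        if part.gene is None:
            continue
        plen = len(part.text)
        m_start0 = off_irb + (spec.ir_len - local0 - plen)
        gd = part.gene
        if len(gd.exons) != 1:
            raise ValueError("multi-exon IR genes unsupported")
        strand = "+" if gd.strand == "-" else "-"
        features.append(
            GeneFeature(
                gd.name, gd.kind, strand,
                [Interval(m_start0 + 1, m_start0 + plen)],
                pseudo_flag=part.pseudo,
            )
        )
        copy_counts[gd.name] = copy_counts.get(gd.name, 0) + 1

    # the junction-spanning ycf1 of Type A/B (single annotated copy)
    if spec.jsa_type in ("A", "B"):
        start0 = off_ssc + spec.ssc_len - (spec.ycf1_len - spec.ycf1_bp_in_ira)
        iv = Interval(start0 + 1, off_ira + spec.ycf1_bp_in_ira)
        features.append(GeneFeature("ycf1", "CDS", "-", [iv]))
        copy_counts["ycf1"] = 1
    statuses["ycf1"] = statuses.get("ycf1", "intact")

    genome = list(lsc_str + irb_str + ssc_str + ira_str)

    # --- planted repeats and tandem arrays --------------------------------
    spacer_map = {
        "lsc": [(off_lsc + a, off_lsc + b) for a, b in lsc_spc],
        "ssc": [(off_ssc + a, off_ssc + b) for a, b in ssc_spc],
    }
    reserved: list[tuple[int, int]] = []

    def claim(region: str, width: int, near: int | None) -> int:
        """Reserve ``width`` bp inside a background spacer; returns 0-based start."""
        slots = spacer_map[region]
        order = sorted(
            range(len(slots)),
            key=lambda i: (
                abs((slots[i][0] + slots[i][1]) // 2 - (near - 1)) if near else rng_plant.integers(1 << 30)
            ),
        )
        for i in order:
            a, b = slots[i]
            if b - a + 1 < width + 4:
                continue
            for _ in range(30):
                s = int(rng_plant.integers(a + 2, b - width))
                # reserve the flanks too: periodicity/extension pinning
                # writes one base either side of a planted element
                if all(s + width + 1 < ra or s - 2 > rb for ra, rb in reserved):
                    reserved.append((s - 2, s + width + 1))
                    return s
        raise ValueError(f"no room to plant a {width} bp element in {region}")

    truth_repeats: list[dict] = []
    for pr in spec.planted_dispersed:
        core = _bg(rng_plant, pr.length, gc)
        other = reverse_complement(core) if pr.direction == "inverted" else core
        other = list(other)
        pos_mut = rng_plant.choice(pr.length, size=pr.mismatches, replace=False)
        for j in pos_mut:
            other[j] = rng_plant.choice([b for b in "ACGT" if b != other[j]])
        other = "".join(other)
        s1 = claim(pr.region1, pr.length, pr.near1)
        s2 = claim(pr.region2, pr.length, pr.near2)
        if s2 < s1:
            s1, s2 = s2, s1
            core, other = (
                (reverse_complement(other), reverse_complement(core))
                if pr.direction == "inverted"
                else (other, core)
            )
        genome[s1 : s1 + pr.length] = core
        genome[s2 : s2 + pr.length] = other
        truth_repeats.append(
            {
                "direction": pr.direction,
                "length": pr.length,
                "mismatches": pr.mismatches,
                "pos1": (s1 + 1, s1 + pr.length),
                "pos2": (s2 + 1, s2 + pr.length),
            }
        )

    truth_tandems: list[dict] = []
    from .repeats import scan_tandem_repeats as _scan_td  # local check below

    for pt in spec.planted_tandem:
        width = pt.unit_len * pt.copies
        s = claim(pt.region, width, None)
        for _attempt in range(30):
            unit = _bg(rng_plant, pt.unit_len, gc)
            if not _primitive(unit):
                continue
            genome[s : s + width] = unit * pt.copies
            # break the periodicity at both flanks so the span is maximal
            left = s - 1
            if genome[left] == genome[left + pt.unit_len]:
                genome[left] = next(
                    b for b in "ACGT" if b != genome[left + pt.unit_len]
                )
            right = s + width
            if genome[right] == genome[right - pt.unit_len]:
                genome[right] = next(
                    b for b in "ACGT" if b != genome[right - pt.unit_len]
                )
            # the realised context must not embed the array in a larger
            # maximal array (which hidden-repeat removal would suppress)
            margin = width + 50
            w_lo = max(0, s - margin)
            window = "".join(genome[w_lo : s + width + margin])
            local, _ = _scan_td(window, unit_max=width + 50)
            target = (s - w_lo + 1, s - w_lo + width)
            if any(
                (t.span.start, t.span.end) == target and t.unit_len == pt.unit_len
                for t in local
            ):
                break
        else:
            raise ValueError("could not realise a planted tandem array")
        truth_tandems.append(
            {
                "unit": unit,
                "unit_len": pt.unit_len,
                "copies": pt.copies,
                "span": (s + 1, s + width),
            }
        )

    # pin the background base flanking every truncation cut so the matched
    # extent of a truncated gene equals the planted extent exactly (a random
    # flank would extend the match with probability 1/4 per base)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def pin(pos0: int, forbidden: str) -> None:
        if genome[pos0] == forbidden:
            genome[pos0] = next(b for b in "ACGT" if b not in (forbidden, genome[pos0]))
        if off_ira <= pos0 < off_ira + spec.ir_len:  # mirror into IRb
            mpos = off_irb + (spec.ir_len - 1 - (pos0 - off_ira))
            genome[mpos] = comp[genome[pos0]]

    for name, lesion in lesions.items():
        if lesion[0] != "truncate" or name in deleted:
            continue
        feat = next(f for f in features if f.name == name)
        keep = len(seqs[name])
        nxt = prelesion[name][keep]
        s0 = min(e.start for e in feat.exons) - 1
        if feat.strand == "+":
            pin(s0 + keep, nxt)
        else:
            pin(s0 - 1, comp[nxt])

    _enforce_exact_ir_bounds(genome, spec.lsc_len, spec.ir_len, spec.ssc_len, features)
    seq = "".join(genome)
    # IRb stays the exact reverse complement of IRa: planting and boundary
    # pinning are restricted to single-copy regions, so this is structural
    record = PlastomeRecord(f"SYN{spec.seed}_{spec.jsa_type}", seq, True, features)

    ycf1_bp = spec.ycf1_len if spec.jsa_type == "C" else spec.ycf1_bp_in_ira
    truth = TruthTable(
        lsc_len=spec.lsc_len,
        ir_len=spec.ir_len,
        ssc_len=spec.ssc_len,
        genome_len=L_total,
        jsa_type=spec.jsa_type,
        ycf1_bp_in_ira=ycf1_bp,
        extra_ir_genes=extra_ir_genes,
        statuses=statuses,
        lesions=lesions,
        copy_counts=copy_counts,
        gene_lengths=gene_lengths,
        repeats=truth_repeats,
        tandems=truth_tandems,
        spacers={
            k: [Interval(a + 1, b + 1) for a, b in v] for k, v in spacer_map.items()
        },
    )
    # lesion genome positions for convenience in tests
    for name, detail in lesion_details.items():
        truth.lesions[name] = truth.lesions[name] + (detail,)
    return record, truth


# ---------------------------------------------------------------------------
# structural history operators


def apply_ir_expansion(
    record: PlastomeRecord,
    qmap: QuadripartiteMap,
    mechanism: str,
    extent: int,
) -> tuple[PlastomeRecord, list[dict]]:
    """Move J_SA into the SSC by ``extent`` bp, duplicating into IRb.

    The incorporated segment (the SSC's last ``extent`` bases) becomes the
    new J_SA-proximal end of IRa, and its reverse complement is appended to
    IRb's SSC-facing end, exactly as copy-repair across the junction would
    do. ``gene_conversion_short`` is capped at 200 bp; ``dsb_long`` is
    unrestricted. The record must be in the canonical frame.
    """
    if mechanism not in ("gene_conversion_short", "dsb_long"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if extent == 0:
        return copy.deepcopy(record), []
    if extent < 0:
        raise ValueError("extent must be >= 0")
    if mechanism == "gene_conversion_short" and extent > 200:
        raise ValueError("gene_conversion_short is limited to 200 bp extents")
    if extent >= qmap.ssc_len:
        raise ValueError("extent would consume the entire SSC")
    if qmap.lsc.start != 1 or qmap.flipped:
        raise ValueError("record must be canonicalized first")
    L = qmap.genome_len
    B = qmap.irb.end  # insertion point: revcomp(segment) goes after base B
    seg_lo = qmap.ssc.end - extent + 1  # 1-based
    seg = record.seq[seg_lo - 1 : qmap.ssc.end]
    new_seq = (
        record.seq[:B] + reverse_complement(seg) + record.seq[B:]
    )
    feats: list[GeneFeature] = []
    dup_sources: list[GeneFeature] = []
    genes_in_seg: list[str] = []
    for f in record.features:
        lo = min(min(e.start, e.end) for e in f.exons)
        hi = max(max(e.start, e.end) for e in f.exons)
        if lo <= B < hi:
            raise ValueError(f"feature {f.name} spans the IRb/SSC junction")
        if hi > B:
            f = replace(
                f,
                exons=[Interval(e.start + extent, e.end + extent, e.wraps) for e in f.exons],
            )
        feats.append(f)
        if hi >= seg_lo and lo <= qmap.ssc.end:  # overlaps the moved segment
            genes_in_seg.append(f.name)
            if lo >= seg_lo and hi <= qmap.ssc.end and len(f.exons) == 1:
                dup_sources.append(f)
    for f in dup_sources:
        e = f.exons[0]
        # original (pre-shift) offsets within the segment
        o1 = (e.start - extent) - seg_lo
        o2 = (e.end - extent) - seg_lo
        m_start = B + (extent - 1 - o2) + 1
        m_end = B + (extent - 1 - o1) + 1
        feats.append(
            replace(
                f,
                strand="+" if f.strand == "-" else "-",
                exons=[Interval(m_start, m_end)],
            )
        )
    new_rec = PlastomeRecord(record.id + f"_exp{extent}", new_seq, True, feats)
    log = [
        {
            "mechanism": mechanism,
            "extent": extent,
            "segment_in_reference": (seg_lo, qmap.ssc.end),
            "genes_incorporated": sorted(set(genes_in_seg)),
        }
    ]
    return new_rec, log


def prepare_expansion(
    record: PlastomeRecord, qmap: QuadripartiteMap, extent: int
) -> PlastomeRecord:
    """Pin the two single-copy bases that become the new inner junction
    flanks after an ``extent`` bp expansion, so that the expanded IR's
    detected length equals the planned extent exactly.

    After expansion the SSC's first base pairs (across the two inner
    junctions) with the base just before the incorporated segment; if they
    happen to be complementary (~1/4 of random backgrounds) exact IR
    detection would extend one base further. Both positions must be
    background spacer; a genic flank raises.
    """
    if extent <= 0:
        return record
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    p_first = qmap.ssc.start  # unchanged by the expansion
    p_last = qmap.ssc.end - extent  # becomes the new SSC's last base
    seq = list(record.seq)
    if seq[p_first - 1] != comp[seq[p_last - 1]]:
        return record
    genic: set[int] = set()
    for f in record.features:
        for e in f.exons:
            genic.update(range(e.start, e.end + 1))
    for pos, other in ((p_last, p_first), (p_first, p_last)):
        if pos not in genic:
            seq[pos - 1] = next(
                b for b in "ACGT"
                if b != comp[seq[other - 1]] and b != seq[pos - 1]
            )
            return PlastomeRecord(record.id, "".join(seq), True, record.features)
    raise ValueError("both junction flanks are genic; cannot pin the boundary")


def strumaria_like_spec(seed: int) -> SynthSpec:
    """A Type C blueprint with the *ndh*-suite degradation pattern of a
    heavily rearranged Amaryllidoideae plastome: 5 pseudogenes (ndhD, ndhH,
    ndhI, ndhJ, ndhK), 4 losses (ndhA, ndhE, ndhF, ndhG), ndhB and ndhC
    intact; ycf1 and rps15 wholly inside the IR next to the truncated,
    stop-less ndhH."""
    return SynthSpec.type_c(
        seed,
        planted_status={
            "ndhJ": ("internal_stop",),
            "ndhD": ("frameshift",),
            "ndhI": ("frameshift",),
            "ndhK": ("frameshift",),
            "ndhA": ("delete",),
            "ndhE": ("delete",),
            "ndhF": ("delete",),
            "ndhG": ("truncate", 0.2),
        },
    )


def scenario_single_expansion(
    seed: int, with_repeat: bool = False
) -> tuple[PlastomeRecord, PlastomeRecord, list[dict]]:
    """Ancestor (Type A) plus a derived genome created by one long
    IR expansion whose boundary falls in the spacer before ycf1's tail.

    With ``with_repeat`` a 17 bp inverted pair (1 mismatch) is planted with
    one copy near the future junction and one near the old junction, so the
    expansion should be labelled repeat-mediated on recovery.
    """
    spec = SynthSpec.type_a(seed, ssc_len=8000, jsa_spacer=250)
    ancestor, truth = build_plastome(spec)
    m = truth.expected_map()
    tail_len = spec.ycf1_len - spec.ycf1_bp_in_ira
    extent = tail_len + 150  # boundary 100 bp into the 250 bp pinned spacer
    if with_repeat:
        rng = np.random.default_rng([seed, 97])
        seq = list(ancestor.seq)
        src0 = m.ssc.end - 77  # 17-mer inside ycf1's tail, near the old J_SA
        core = "".join(seq[src0 : src0 + 17])
        other = list(reverse_complement(core))
        j = int(rng.integers(17))
        other[j] = str(rng.choice([b for b in "ACGT" if b != other[j]]))
        spacer_start0 = m.ssc.end - tail_len - 250  # 0-based
        dest0 = spacer_start0 + 20  # stays on the SSC side of the new J_SA
        seq[dest0 : dest0 + 17] = other
        ancestor = PlastomeRecord(ancestor.id, "".join(seq), True, ancestor.features)
    ancestor = prepare_expansion(ancestor, m, extent)
    derived, _log = apply_ir_expansion(ancestor, m, "dsb_long", extent)
    # mechanism is asserted only when a repeat was planted: the random
    # background can legitimately contain a chance junction-window repeat,
    # which the inference should (and does) report
    events = [
        {
            "size": extent,
            "genes": ["ycf1"],
            "mechanism": "repeat_mediated" if with_repeat else None,
        }
    ]
    return ancestor, derived, events


def scenario_two_event_expansion(
    seed: int,
) -> tuple[PlastomeRecord, PlastomeRecord, list[dict]]:
    """Ancestor (Type A) and a derived genome built by a long expansion,
    a gene-loss deletion next to the new junction, then a 45 bp short
    expansion sourcing a spacer — the two-step history behind a Type C-like
    arrangement. Recovery should report two events: the 45 bp one nearest
    J_SA, then the long one."""
    spec = SynthSpec.type_a(
        seed, ssc_len=8000, jsa_spacer=250, pinned_spacers={"ndhH": 60, "ndhA": 80}
    )
    ancestor, truth = build_plastome(spec)
    m = truth.expected_map()
    ndhh = ancestor.features_named("ndhH")[0]
    hi = max(e.end for e in ndhh.exons)
    lo = min(e.start for e in ndhh.exons)
    e1 = m.ssc.end - hi - 30  # boundary mid-way through the pinned spacer
    ancestor = prepare_expansion(ancestor, m, e1)
    # pin the bases flanking the future deletion against the long event's
    # boundary bases, so the reconstructed event split is exact: a chance
    # base match would otherwise move one base between the two events
    seq = list(ancestor.seq)
    for p_del, p_seg in ((lo - 16, hi + 30), (lo - 15, hi + 31)):
        if seq[p_del - 1] == seq[p_seg - 1]:
            seq[p_del - 1] = next(
                b for b in "ACGT" if b not in (seq[p_seg - 1], seq[p_del - 1])
            )
    ancestor = PlastomeRecord(ancestor.id, "".join(seq), True, ancestor.features)
    d1, _ = apply_ir_expansion(ancestor, m, "dsb_long", e1)
    m1 = canonical_map(m.lsc_len, m.ir_len + e1, m.ssc_len - e1)
    ndhh1 = d1.features_named("ndhH")[0]
    lo1 = min(e.start for e in ndhh1.exons)
    d2 = delete_region(d1, Interval(lo1 - 15, m1.ssc.end))
    del_width = m1.ssc.end - (lo1 - 15) + 1
    m2 = canonical_map(m.lsc_len, m.ir_len + e1, m.ssc_len - e1 - del_width)
    d2 = prepare_expansion(d2, m2, 45)
    d3, _ = apply_ir_expansion(d2, m2, "gene_conversion_short", 45)
    events = [
        {"size": 45, "genes": [], "mechanism": None},
        {"size": e1, "genes": ["rps15", "ycf1"], "mechanism": None},
    ]
    return ancestor, d3, events


def delete_region(record: PlastomeRecord, interval: Interval) -> PlastomeRecord:
    """Remove a block of sequence (gene-loss model), shifting coordinates.

    Features wholly inside the block are dropped; a feature partially
    overlapping it raises, since a clean loss scenario should not shear
    annotations.
    """
    if interval.wraps:
        raise ValueError("wrapping deletions are not supported")
    interval.validate(record.length)
    a, b = interval.start, interval.end
    width = b - a + 1
    feats = []
    for f in record.features:
        lo = min(min(e.start, e.end) for e in f.exons)
        hi = max(max(e.start, e.end) for e in f.exons)
        if lo >= a and hi <= b:
            continue
        if hi >= a and lo <= b:
            raise ValueError(f"deletion shears feature {f.name}")
        if lo > b:
            f = replace(
                f,
                exons=[Interval(e.start - width, e.end - width, e.wraps) for e in f.exons],
            )
        feats.append(f)
    seq = record.seq[: a - 1] + record.seq[b:]
    return PlastomeRecord(record.id + "_del", seq, True, feats)
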