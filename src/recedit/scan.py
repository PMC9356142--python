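"""Database-generation scans: genome-wide, start/stop-codon, and variant windows.

Three drivers share one engine: extract a design window, constrain where
the first cut may fall, run the recursive search, and emit one record per
qualifying site. Records embed the full serialized cascade, so a scan row
is bit-identical to running the search directly on that window.

* ``scan_genome`` evaluates every enumerable guide as a potential entry
  point, keeps those whose predicted outcome spectrum is concentrated
  enough (top-2 frequency sum >= the entry threshold), and emits sites
  classified recursive, deduplicating overlapping hits.
* ``scan_cds_ends`` builds one window per deduplicated start/stop codon
  from a GFF3 annotation — the endogenous-tagging use case, where the knock-in
  must land at a coding terminus.
* ``scan_variants`` builds a +/-50 bp window per VCF variant (indels longer
  than 50 bp are excluded), treats the variant-installed (or, in revert
  mode, variant-corrected) sequence as the HDR allele, and requires the
  first cut near the variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import DonorSpec, IndelOutcome, SequenceWindow, Substitution
from .guides import FilterConfig, OfftargetIndex, annotate, enumerate_guides
from .ioutils import cascade_to_json, cascade_to_tsv, read_fasta
from .predict import PredictorParams, concentration, predict_outcomes
from .search import Cascade, SearchConfig, SiteReport, build_report, run_recursion

__all__ = [
    "ScanJob",
    "DatabaseRecord",
    "scan_genome",
    "scan_cds_ends",
    "scan_variants",
    "filter_variants",
    "records_to_tsv",
]

log = logging.getLogger("recedit.scan")

DB_COLUMNS = [
    "locus_id",
    "contig",
    "window_start",
    "window_end",
    "feature",
    "n_levels",
    "is_recursive",
    "overall_rank_score",
    "retargeting_efficiency_0",
    "guides_per_level",
]


@dataclass
class ScanJob:
    """Inputs and configuration for one scan run.

    ``window_half_width`` defaults depend on the mode: 50 for genome and
    variant windows, 30 around codons. ``step`` coarsens the genome mode by
    evaluating every step-th candidate guide. ``dedup_radius`` collapses
    genome records whose A cuts are within this many bp, keeping the best
    scoring. ``revert`` flips the variant scan between installing the
    variant (HDR allele = variant sequence) and correcting it.
    """

    mode: str
    genome: str = ""
    annotation: str = ""
    variants: str = ""
    window_half_width: int | None = None
    step: int = 1
    dedup_radius: int = 5
    revert: bool = False
    search_config: SearchConfig = field(default_factory=SearchConfig)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    predictor_params: PredictorParams = field(default_factory=PredictorParams)

    def __post_init__(self) -> None:
        if self.mode not in ("genome", "cds_ends", "variants"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.window_half_width is None:
            self.window_half_width = 30 if self.mode == "cds_ends" else 50


@dataclass(frozen=True)
class DatabaseRecord:
    """One qualifying site: identity, flattened report fields, serialized cascade."""

    locus_id: str
    contig: str
    window_start: int
    window_end: int
    feature: str
    report: SiteReport
    cascade_json: str
    cascade_tsv: str

    @property
    def overall_rank_score(self) -> float:
        return self.report.overall_rank_score

    def row(self) -> dict:
        rep = self.report
        return {
            "locus_id": self.locus_id,
            "contig": self.contig,
            "window_start": self.window_start,
            "window_end": self.window_end,
            "feature": self.feature,
            "n_levels": rep.cascade.n_levels,
            "is_recursive": rep.is_recursive,
            "overall_rank_score": round(rep.overall_rank_score, 10),
            "retargeting_efficiency_0": round(
                rep.retargeting_efficiency_per_level[0] if rep.retargeting_efficiency_per_level else 0.0, 10
            ),
            "guides_per_level": ";".join(
                ",".join(sel.label for sel in lvl.selections) for lvl in rep.cascade.levels
            ),
        }


def records_to_tsv(records) -> str:
    lines = ["\t".join(DB_COLUMNS)]
    for r in records:
        row = r.row()
        lines.append("\t".join(str(row[c]) for c in DB_COLUMNS))
    return "\n".join(lines) + "\n"


def _sorted_records(records):
    return sorted(records, key=lambda r: (-r.overall_rank_score, r.contig, r.window_start))


def _default_donor(window_seq: str, cut_local: int, arm: int = 45) -> DonorSpec:
    """ssODN-style donor installing a 3-bp GAT insertion at the cut site."""
    edit = IndelOutcome(kind="insertion", start=cut_local, length=3, inserted_seq="GAT")
    return DonorSpec.from_edit(window_seq, edit, homology_arm_length=arm)


def _make_record(locus_id, contig, wstart, wend, feature, cascade) -> DatabaseRecord:
    report = build_report(cascade)
    return DatabaseRecord(
        locus_id=locus_id,
        contig=contig,
        window_start=wstart,
        window_end=wend,
        feature=feature,
        report=report,
        cascade_json=cascade_to_json(cascade, report),
        cascade_tsv=cascade_to_tsv(cascade, report),
    )


def _load_genome(job: ScanJob) -> dict:
    try:
        return read_fasta(job.genome)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read genome FASTA {job.genome!r}: {exc}") from exc


def scan_genome(job: ScanJob):
    """Genome-wide search for Recursive-Editing-amenable sites.

    Every enumerated guide is a candidate entry point; the cheap entry gate
    (outcome concentration at its cut) runs before the expensive recursion.
    Only sites classified recursive are emitted; overlapping hits within
    ``dedup_radius`` bp collapse to the best-scoring.
    """
    contigs = _load_genome(job)
    hw = job.window_half_width
    ot_index = OfftargetIndex([(name, seq) for name, seq in contigs.items()])
    cfg, filters, params = job.search_config, job.filter_config, job.predictor_params
    hits = []  # (contig, a_cut, record)
    for name in contigs:
        seq = contigs[name]
        if set(seq) - set("ACGT"):
            log.warning("contig %s contains non-ACGT bases; used for background only", name)
            continue
        guides = enumerate_guides(seq, name)[:: max(job.step, 1)]
        for g in guides:
            if g.cut_index - hw < 0 or g.cut_index + hw > len(seq):
                log.debug("skipping %s: window truncated at contig edge", g.guide_id)
                continue
            try:
                dist = predict_outcomes(seq, g.cut_index, params)
            except ValueError:
                continue
            if concentration(dist, 2) < cfg.entry_concentration_min:
                continue
            wstart = g.cut_index - hw
            window = SequenceWindow(name, wstart, seq[wstart : g.cut_index + hw])
            cut_local = g.cut_index - wstart
            donor = _default_donor(window.seq, cut_local)
            # annotate in genomic coordinates (correct off-target exclusion),
            # then shift into the window frame
            a_local = _shift_guide(annotate(g, ot_index, filters.mm_max), -wstart, name)
            cascade = run_recursion(
                window, donor, params, filters, cfg, a_guide=a_local, ot_index=ot_index
            )
            if cascade.n_levels == 0:
                continue
            report = build_report(cascade)
            if not report.is_recursive:
                continue
            rec = _make_record(
                f"{name}:{wstart}-{wstart + len(window.seq)}", name, wstart,
                wstart + len(window.seq), f"cut={g.cut_index}", cascade,
            )
            hits.append((name, g.cut_index, rec))
    return _sorted_records(_dedup(hits, job.dedup_radius))


def _shift_guide(g, offset, source_id):
    from dataclasses import replace

    return replace(
        g, start=g.start + offset, cut_index=g.cut_index + offset,
        guide_id=f"{source_id}:{g.start + offset}{g.strand}", source_id=source_id,
    )


def _dedup(hits, radius):
    """Collapse records whose A cuts on the same contig are within radius bp."""
    best: list = []
    for name, cut, rec in sorted(
        hits, key=lambda h: (-h[2].overall_rank_score, h[0], h[1])
    ):
        if any(n == name and abs(c - cut) <= radius for n, c, _ in best):
            continue
        best.append((name, cut, rec))
    return [rec for _, _, rec in best]


def _iter_codons(annotation_path):
    """Deduplicated (contig, start0, end0, kind, gene) codons from a GFF3."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(annotation_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        log.warning("annotation %s contains no parseable features", annotation_path)
        return []
    seen = set()
    out = []
    for kind in ("start_codon", "stop_codon"):
        for feat in db.features_of_type(kind, order_by=("seqid", "start")):
            key = (feat.seqid, feat.start - 1, feat.end, kind)
            if key in seen:  # isoforms sharing the codon collapse to one window
                continue
            seen.add(key)
            gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or ["?"])[0]
            out.append((feat.seqid, feat.start - 1, feat.end, kind, gene))
    return out


def scan_cds_ends(job: ScanJob):
    """One design window per deduplicated start/stop codon (endogenous tagging)."""
    contigs = _load_genome(job)
    ot_index = OfftargetIndex([(name, seq) for name, seq in contigs.items()])
    cfg, filters, params = job.search_config, job.filter_config, job.predictor_params
    codons = _iter_codons(job.annotation)
    if not codons:
        log.warning("annotation %s contains no start_codon/stop_codon features", job.annotation)
        return []
    hw = job.window_half_width
    records = []
    for contig, cstart, cend, kind, gene in codons:
        if contig not in contigs:
            log.warning("codon %s on unknown contig %s skipped", gene, contig)
            continue
        seq = contigs[contig]
        wstart, wend = cstart - hw, cend + hw
        if wstart < 0 or wend > len(seq):
            log.info("codon window %s:%d-%d truncated at contig edge; skipped", contig, wstart, wend)
            continue
        window = SequenceWindow(contig, wstart, seq[wstart:wend])
        mid = (cstart + cend) // 2 - wstart
        donor = _default_donor(window.seq, mid)
        a_range = (cstart - wstart - filters.proximity_bp, cend - wstart + filters.proximity_bp)
        cascade = run_recursion(
            window, donor, params, filters, cfg, a_cut_range=a_range, ot_index=ot_index
        )
        if cascade.n_levels == 0:
            continue
        records.append(
            _make_record(f"{gene}:{kind}", contig, wstart, wend, f"{kind}:{gene}", cascade)
        )
    return _sorted_records(records)


def _iter_variants(vcf_path):
    """(contig, pos0, vid, ref, alt) records from a VCF, malformed ones skipped."""
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(vcf_path)):
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        if not v.ALT:
            log.warning("variant %s has no ALT; skipped", vid)
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if ref == alt:
            log.warning("variant %s has REF == ALT; skipped as malformed", vid)
            continue
        if set(ref + alt) - set("ACGT"):
            log.warning("variant %s has non-ACGT alleles; skipped", vid)
            continue
        out.append((v.CHROM, v.POS - 1, vid, ref, alt))
    return out


def filter_variants(variants, max_indel: int = 50):
    """Length filter: keep variants with |len(REF) - len(ALT)| <= max_indel."""
    kept = []
    for contig, pos, vid, ref, alt in variants:
        if abs(len(ref) - len(alt)) > max_indel:
            log.info("variant %s indel > %d bp; excluded", vid, max_indel)
            continue
        kept.append((contig, pos, vid, ref, alt))
    return kept


def scan_variants(job: ScanJob):
    """Design windows around VCF variants; the HDR allele installs (or
    reverts) the variant. Indels longer than 50 bp are excluded."""
    contigs = _load_genome(job)
    ot_index = OfftargetIndex([(name, seq) for name, seq in contigs.items()])
    cfg, filters, params = job.search_config, job.filter_config, job.predictor_params
    hw = job.window_half_width
    records = []
    for contig, pos, vid, ref, alt in filter_variants(_iter_variants(job.variants)):
        if contig not in contigs:
            log.warning("variant %s on unknown contig %s skipped", vid, contig)
            continue
        seq = contigs[contig]
        wstart, wend = pos - hw, pos + len(ref) + hw
        if wstart < 0 or wend > len(seq):
            log.info("variant window %s truncated at contig edge; skipped", vid)
            continue
        window = SequenceWindow(contig, wstart, seq[wstart:wend])
        local = pos - wstart
        if window.seq[local : local + len(ref)] != ref:
            log.warning("variant %s REF does not match the genome; skipped", vid)
            continue
        if job.revert:
            # design on the variant sequence; HDR restores the reference
            var_seq = window.seq[:local] + alt + window.seq[local + len(ref) :]
            design_window = SequenceWindow(contig, wstart, var_seq)
            donor = DonorSpec.from_substitution(var_seq, local, alt, ref)
        else:
            design_window = window
            donor = DonorSpec.from_substitution(window.seq, local, ref, alt)
        a_range = (local - filters.proximity_bp, local + len(ref) + filters.proximity_bp)
        cascade = run_recursion(
            design_window, donor, params, filters, cfg, a_cut_range=a_range, ot_index=ot_index
        )
        if cascade.n_levels == 0:
            continue
        records.append(_make_record(vid, contig, wstart, wend, f"variant:{vid}", cascade))
    return _sorted_records(records)
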