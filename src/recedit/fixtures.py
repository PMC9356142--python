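"""Synthetic fixture generator: mini-genome, annotation, variants, truth table.

Everything downstream of the generator — the scans, the recursion, the
simulator — is exercised against genomes built here, so the generator is
first-class, verified code, not a loose helper. It emulates the three
kinds of real input the tool consumes:

* a multi-contig genome FASTA with *planted constructs* whose cascade
  structure is known by design and verified at generation time by running
  the recursive search on each planted window;
* a GFF3 with gene/start_codon/stop_codon features (including redundant
  isoform entries sharing a codon, to exercise deduplication);
* a VCF of SNVs and short indels, plus one >50 bp deletion and one
  malformed record, to exercise the variant filters.

Construct designs
-----------------
``mh_deletion_chain``
    A 5x3-bp tandem repeat. Each cut's dominant outcome deletes one repeat
    unit with long flanking microhomology, so the site supports three
    successive 3-bp alt-EJ deletions (levels A/B/C), clears the genome-scan
    entry gate, and classifies recursive.
``plus1_dup``
    A 14-nt period-6 repeat cut near the window edge. The dominant outcome
    is a 6-bp microhomology deletion carrying >25% of the indel mass
    (recursive), and the +1 duplication of the cut-adjacent base is the
    rank-2 predicted outcome. The bundled model never gives the +1 class
    enough aggregate mass to warrant its own retargeting guide, so the
    expected cascade is two levels with B1 on the deletion child.
``non_recursive``
    A repeat-suppressed window with a single planted PAM: the outcome
    spectrum is dispersed, no retargeting guide reaches the minimum
    targeted mass, and the site classifies non-recursive.

Flanks around each construct are PAM-stripped so the planted guide is the
only entry point; the whole background is scrubbed of tandem repeats long
enough to create accidental entry points. ssODN-style donors install a
3-bp GAT insertion at each planted cut, with 45-bp homology arms.

Generation is byte-reproducible from the seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

from .core import DonorSpec, IndelOutcome, SequenceWindow
from .guides import enumerate_guides
from .ioutils import write_fasta
from .predict import PredictorParams, concentration, predict_outcomes
from .search import SearchConfig, build_report, run_recursion

__all__ = ["FixtureSpec", "GenerationError", "PlantedSite", "generate_fixtures"]


class GenerationError(RuntimeError):
    """Raised when constructs collide or a planted design cannot be realised."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture set.

    ``planted_constructs`` lists {"type": ..., "count": ...} entries; types
    are ``plus1_dup``, ``mh_deletion_chain`` and ``non_recursive``. Defaults
    give three scan-eligible recursive sites, one plus1_dup and one
    non-recursive control on a 4 x 5 kb genome.
    """

    seed: int
    n_contigs: int = 4
    contig_length: int = 5000
    planted_constructs: tuple = (
        {"type": "mh_deletion_chain", "count": 3},
        {"type": "plus1_dup", "count": 1},
        {"type": "non_recursive", "count": 1},
    )
    gene_count: int = 4
    variant_count: int = 6

    def __post_init__(self) -> None:
        if self.contig_length < 1200:
            raise ValueError("contig_length must be >= 1200 to hold constructs")
        for entry in self.planted_constructs:
            if entry["type"] not in ("plus1_dup", "mh_deletion_chain", "non_recursive"):
                raise ValueError(f"unknown construct type {entry['type']!r}")


@dataclass(frozen=True)
class PlantedSite:
    """Truth-table entry for one planted construct."""

    construct: str
    contig: str
    window_start: int
    window_end: int
    a_cut: int  # genomic coordinate of the designed first cut
    expected_levels: int
    expected_dominant_outcomes: tuple  # label per level, e.g. ("-3 bp del", ...)
    expected_recursive: bool
    scan_eligible: bool
    donor_edit: dict


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = "ACGT"


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _rand_nopam(rng: random.Random, n: int) -> str:
    """Random sequence without GG/CC dinucleotides (no SpCas9 PAMs)."""
    while True:
        s = _rand_seq(rng, n)
        if "GG" not in s and "CC" not in s:
            return s


def _background_seq(rng: random.Random, n: int, max_period: int = 30, max_run: int = 4) -> list:
    """Random background with bounded tandem microhomology.

    While sampling left to right, a letter is excluded whenever choosing it
    would extend a repeat run (match at distance d <= max_period) beyond
    ``max_run`` consecutive positions. This caps accidental microhomology
    at 4 nt, so the random background can never produce the concentrated
    deletion classes that would create stray recursive entry points.
    """
    seq: list = []
    runs = [0] * (max_period + 1)  # current match-run length per distance
    for t in range(n):
        banned = set()
        for d in range(1, min(max_period, t) + 1):
            if runs[d] >= max_run:
                banned.add(seq[t - d])
        choices = [b for b in _BASES if b not in banned] or list(_BASES)
        b = choices[rng.randrange(len(choices))]
        seq.append(b)
        for d in range(1, min(max_period, t) + 1):
            runs[d] = runs[d] + 1 if seq[t - d] == b else 0
    return seq


def _strip_pams(seq: list, lo: int, hi: int, rng: random.Random) -> None:
    """Remove GG/CC dinucleotides from seq[lo:hi] (clamped), rewriting bases."""
    lo, hi = max(lo, 0), min(hi, len(seq))
    dirty = True
    while dirty:
        dirty = False
        for i in range(lo, hi - 1):
            pair = seq[i] + seq[i + 1]
            if pair in ("GG", "CC"):
                seq[i + 1] = rng.choice("AT")
                dirty = True


# ---------------------------------------------------------------------------
# construct designs
#
# Each designer returns (core_sequence, design) where design records the A
# cut, the truth window (relative to the core start) and the expected
# cascade structure. Designers only run cheap spectral checks; the full
# recursion is verified after planting.


def _design_chain(rng: random.Random, used_units: set = frozenset()):
    """6x3-bp tandem array with a single plus-strand PAM after the array.

    The -3 deletion (one repeat unit, microhomology capped at 15) dominates
    with ~40% of the indel mass and the -6 ranks second, so the site clears
    the 0.5 entry-concentration gate even against full-contig background.
    Retargeting guides span progressively shorter arrays plus left flank;
    the flank's last 12 nt are chosen per-position distinct from the array
    phase, so those guides sit >2 mismatches from the wildtype site and
    survive exact off-target counting. Units are unique per genome so two
    arrays are never within 2 mismatches of each other.
    """
    units = ["CTA", "TCA", "ACT", "CAT", "TGA", "AGT", "GTA", "ATG", "TAC"]
    avail = [u for u in units if u not in used_units]
    for _ in range(300):
        u = avail[rng.randrange(len(avail))]
        left = _rand_nopam(rng, 30)
        # rewrite the 12 nt abutting the array: each differs from the unit
        # char at its phase (keeps dinucleotides PAM-free)
        tail = list(left[-12:])
        for j in range(12):
            phase = (j - 12) % 3
            choices = [b for b in _BASES if b != u[phase]]
            tail[j] = choices[rng.randrange(len(choices))]
        left = left[:-12] + "".join(tail)
        right = "TGG" + _rand_nopam(rng, 27)
        core = left + u * 6 + right
        if core.count("GG") != 1 or "CC" in core:
            continue
        a_cut = len(left) + 18 - 3  # protospacer ends at the array end, PAM just after
        dist = predict_outcomes(core, a_cut)
        top = dist.outcomes[0]
        if not (top.kind == "deletion" and top.length == 3 and top.freq > 0.33):
            continue
        if concentration(dist, 2) < 0.55:
            continue
        design = {
            "a_cut": a_cut,
            "window": (a_cut - 50, a_cut + 50),
            "levels": 3,
            "dominant": ("-3 bp del", "-3 bp del"),
            "rank2_at_entry": None,
            "recursive": True,
            "scan_eligible": True,
            "unit": u,
        }
        return core, design
    raise GenerationError("could not realise an mh_deletion_chain construct")


def _design_plus1(rng: random.Random):
    """14-nt period-6 run cut near the window edge via a minus-strand guide.

    The window *is* the core, so the cut sits at local index 6: the short
    left arm suppresses the deletion background enough for the planted 6-bp
    microhomology deletion to carry >27% of the mass, with the +1
    duplication as the rank-2 outcome.
    """
    for _ in range(3000):
        q = _rand_nopam(rng, 6)
        run = q + q + q[:2]
        right = _rand_nopam(rng, 37)
        core = "CCA" + run + right
        if core.count("CC") != 1 or "GG" in core:
            continue
        a_cut = 6
        dist = predict_outcomes(core, a_cut)
        top, second = dist.outcomes[0], dist.outcomes[1]
        if not (top.kind == "deletion" and top.length == 6 and top.freq > 0.27):
            continue
        if not (second.kind == "insertion" and second.length == 1 and second.freq >= 0.02):
            continue
        design = {
            "a_cut": a_cut,
            "window": (0, len(core)),
            "levels": 2,
            "dominant": ("-6 bp del",),
            "rank2_at_entry": "+1 bp ins",
            "recursive": True,
            "scan_eligible": False,
        }
        return core, design
    raise GenerationError("could not realise a plus1_dup construct")


def _design_non_recursive(rng: random.Random):
    """Dispersed-spectrum control: one planted PAM, repeat-free context."""
    for _ in range(500):
        left = _rand_nopam(rng, 30)
        mid = _rand_nopam(rng, 15)
        right = "TGG" + _rand_nopam(rng, 27)
        core = left + mid + right
        if core.count("GG") != 1 or "CC" in core:
            continue
        a_cut = len(left) + 15 - 3
        dist = predict_outcomes(core, a_cut)
        if concentration(dist, 2) > 0.12:  # keeps efficiency far below 0.20
            continue
        design = {
            "a_cut": a_cut,
            "window": (a_cut - 50, a_cut + 50),
            "levels": 1,
            "dominant": (),
            "rank2_at_entry": None,
            "recursive": False,
            "scan_eligible": False,
        }
        return core, design
    raise GenerationError("could not realise a non_recursive construct")


_DESIGNERS = {
    "mh_deletion_chain": _design_chain,
    "plus1_dup": _design_plus1,
    "non_recursive": _design_non_recursive,
}


def _verify_construct(ctype, contig_seq, contig_id, core_start, design):
    """Run the real recursive search on the planted window; the truth table
    only records what this verification reproduced. Returns None if the
    planted construct does not behave as designed (caller redraws)."""
    a_cut = core_start + design["a_cut"]
    wstart = core_start + design["window"][0]
    wend = core_start + design["window"][1]
    if wstart < 0 or wend > len(contig_seq):
        return None
    window = SequenceWindow(contig_id, wstart, contig_seq[wstart:wend])
    cut_local = a_cut - wstart
    edit = IndelOutcome(kind="insertion", start=cut_local, length=3, inserted_seq="GAT")
    donor = DonorSpec.from_edit(window.seq, edit)
    cascade = run_recursion(window, donor)
    report = build_report(cascade)
    if cascade.n_levels != design["levels"]:
        return None
    if report.is_recursive != design["recursive"]:
        return None
    a_sel = cascade.levels[0].selections[0]
    if a_sel.guide.cut_index != cut_local:
        return None
    for lvl_i in range(1, cascade.n_levels):
        top_sel = cascade.levels[lvl_i].selections[0]
        allele = top_sel.targeted_alleles[0]
        if allele.lineage[-1][1].label != design["dominant"][lvl_i - 1]:
            return None
    if design["rank2_at_entry"] is not None:
        dist = predict_outcomes(window.seq, cut_local)
        if dist.outcomes[1].label != design["rank2_at_entry"]:
            return None
    if design["scan_eligible"]:
        dist = predict_outcomes(contig_seq, a_cut)
        if concentration(dist, 2) < SearchConfig().entry_concentration_min:
            return None
    return PlantedSite(
        construct=ctype,
        contig=contig_id,
        window_start=wstart,
        window_end=wend,
        a_cut=a_cut,
        expected_levels=design["levels"],
        expected_dominant_outcomes=tuple(design["dominant"]),
        expected_recursive=design["recursive"],
        scan_eligible=design["scan_eligible"],
        donor_edit={"kind": "insertion", "start": a_cut, "length": 3, "inserted_seq": "GAT"},
    )


# ---------------------------------------------------------------------------
# gene and variant placement


def _place_genes(contigs, layout, rng):
    """Plant gene models: ATG start (with a PAM-proximal cut) and TAA stop
    (PAM-stripped neighbourhood, so tagging scans hit only the start)."""
    genes = []
    for gi, (contig_id, pos) in enumerate(layout):
        seq = contigs[contig_id]
        name = f"gene{gi + 1}"
        # start codon with a guide cutting 1 nt into it: TGG PAM 4 nt downstream
        seq[pos : pos + 3] = list("ATG")
        seq[pos + 4 : pos + 7] = list("TGG")
        stop = pos + 120
        seq[stop : stop + 3] = list("TAA")
        _strip_pams(seq, stop - 30, stop + 33, rng)
        genes.append({"name": name, "contig": contig_id, "start": pos, "stop": stop})
    return genes


def _write_gff3(path, genes) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g['name']};gene_id={g['name']};gene_name={g['name']}"
        s, e = g["start"] + 1, g["stop"] + 3
        lines.append(
            "\t".join([g["contig"], "recedit", "gene", str(s), str(e), ".", "+", ".", attrs])
        )
        for iso in ("t1", "t2") if g is genes[0] else ("t1",):
            # two isoforms of gene 1 share both codons: exercises deduplication
            ta = f"ID={g['name']}.{iso}.start;Parent={g['name']};transcript_id={g['name']}.{iso};gene_name={g['name']}"
            lines.append(
                "\t".join(
                    [g["contig"], "recedit", "start_codon", str(s), str(s + 2), ".", "+", ".", ta]
                )
            )
            tb = ta.replace(".start", ".stop")
            lines.append(
                "\t".join(
                    [
                        g["contig"], "recedit", "stop_codon",
                        str(g["stop"] + 1), str(g["stop"] + 3), ".", "+", ".", tb,
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _place_variants(contigs, layout, rng):
    """SNVs/short indels near planted PAMs, one >50 bp deletion, one malformed."""
    variants = []
    for vi, (contig_id, pos) in enumerate(layout):
        seq = contigs[contig_id]
        seq[pos + 4 : pos + 7] = list("TGG")  # guide cutting at pos+1, within reach
        ref = seq[pos]
        if vi == 0:
            alt = rng.choice([b for b in _BASES if b != ref])
            variants.append((contig_id, pos, f"snv{vi + 1}", ref, alt))
        elif vi == 1:
            variants.append((contig_id, pos, "ins1", ref, ref + _rand_seq(rng, 3)))
        elif vi == 2:
            ref4 = "".join(seq[pos : pos + 4])
            variants.append((contig_id, pos, "del1", ref4, ref4[0]))
        else:
            alt = rng.choice([b for b in _BASES if b != ref])
            variants.append((contig_id, pos, f"snv{vi + 1}", ref, alt))
    # one >50 bp deletion: exercises the length filter
    contig_id = layout[0][0]
    pos = 200
    seq = contigs[contig_id]
    big_ref = "".join(seq[pos : pos + 61])
    variants.append((contig_id, pos, "bigdel", big_ref, big_ref[0]))
    variants.sort(key=lambda v: (v[0], v[1]))
    return variants


def _write_vcf(path, variants, contigs=None) -> None:
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SYN,Number=0,Type=Flag,Description="Synthetic fixture variant">',
    ]
    for name, seq in (contigs or {}).items():
        header.append(f"##contig=<ID={name},length={len(seq)}>")
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = [
        f"{c}\t{p + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\tSYN" for c, p, vid, ref, alt in variants
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header + rows) + "\n")


# ---------------------------------------------------------------------------
# top-level generation


def generate_fixtures(spec: FixtureSpec, out_dir) -> dict:
    """Write genome.fa, annotation.gff3, variants.vcf, donors.json and
    truth.json/tsv under ``out_dir``; returns paths and the truth table.

    Same spec (same seed) twice -> byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    contigs = {
        f"ctg{i + 1}": _background_seq(rng, spec.contig_length) for i in range(spec.n_contigs)
    }

    # construct slots: fixed offsets, round-robin over contigs
    wanted = [
        entry["type"] for entry in spec.planted_constructs for _ in range(entry["count"])
    ]
    slot_positions = [700 + 900 * k for k in range(3)]
    slots = [
        (f"ctg{(i % spec.n_contigs) + 1}", slot_positions[i // spec.n_contigs])
        for i in range(len(wanted))
    ]
    if len(wanted) > spec.n_contigs * len(slot_positions):
        raise GenerationError("too many constructs for the genome size")
    if spec.contig_length < slot_positions[min(len(wanted) - 1, 2)] + 300:
        raise GenerationError("contig_length too small for the construct layout")

    sites = []
    used_units: set = set()
    for ctype, (contig_id, pos) in zip(wanted, slots):
        seq = contigs[contig_id]
        site = None
        for _ in range(40):
            if ctype == "mh_deletion_chain":
                core, design = _design_chain(rng, used_units)
            else:
                core, design = _DESIGNERS[ctype](rng)
            candidate = list(seq)
            candidate[pos : pos + len(core)] = list(core)
            _strip_pams(candidate, pos - 60, pos, rng)
            _strip_pams(candidate, pos + len(core), pos + len(core) + 60, rng)
            site = _verify_construct(ctype, "".join(candidate), contig_id, pos, design)
            if site is not None:
                contigs[contig_id] = candidate
                if "unit" in design:
                    used_units.add(design["unit"])
                break
        if site is None:
            raise GenerationError(f"failed to plant a verified {ctype} construct at {contig_id}:{pos}")
        sites.append(site)

    # genes and variants live on the upper half of each contig, away from constructs
    gene_layout = [
        (f"ctg{(i % spec.n_contigs) + 1}", 3400 + 300 * (i // spec.n_contigs))
        for i in range(spec.gene_count)
    ]
    genes = _place_genes(contigs, gene_layout, rng)
    var_layout = [
        (f"ctg{(i % spec.n_contigs) + 1}", 4400 + 120 * (i // spec.n_contigs))
        for i in range(spec.variant_count)
    ]
    variants = _place_variants(contigs, var_layout, rng)

    contig_strs = {name: "".join(seq) for name, seq in contigs.items()}
    _check_unique_23mers(contig_strs, sites)
    _final_verify(contig_strs, sites)

    genome_path = out / "genome.fa"
    gff_path = out / "annotation.gff3"
    vcf_path = out / "variants.vcf"
    write_fasta(genome_path, contig_strs)
    _write_gff3(gff_path, genes)
    _write_vcf(vcf_path, variants, contig_strs)

    truth = [
        {
            "construct": s.construct,
            "contig": s.contig,
            "window_start": s.window_start,
            "window_end": s.window_end,
            "a_cut": s.a_cut,
            "expected_levels": s.expected_levels,
            "expected_dominant_outcomes": list(s.expected_dominant_outcomes),
            "expected_recursive": s.expected_recursive,
            "scan_eligible": s.scan_eligible,
            "donor_edit": s.donor_edit,
        }
        for s in sites
    ]
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    tsv_cols = list(truth[0].keys()) if truth else []
    with open(out / "truth.tsv", "w") as fh:
        fh.write("\t".join(tsv_cols) + "\n")
        for t in truth:
            fh.write("\t".join(json.dumps(t[c]) if isinstance(t[c], (list, dict)) else str(t[c]) for c in tsv_cols) + "\n")
    donors = [
        {"contig": s.contig, "a_cut": s.a_cut, "edit": s.donor_edit, "homology_arm_length": 45}
        for s in sites
    ]
    (out / "donors.json").write_text(json.dumps(donors, indent=2, sort_keys=True) + "\n")

    return {
        "genome": genome_path,
        "annotation": gff_path,
        "variants": vcf_path,
        "truth": out / "truth.json",
        "donors": out / "donors.json",
        "sites": sites,
        "genes": genes,
        "variant_records": variants,
        "contigs": contig_strs,
    }


def _cascade_structure(cascade) -> tuple:
    """Structural fingerprint: guides, labels, masses and classification.

    Retargeting scores are excluded — the one-step look-ahead legitimately
    shifts with the off-target background, but the selected guides must not.
    """
    rep = build_report(cascade)
    return (
        tuple(
            tuple(
                (
                    sel.label,
                    sel.guide.protospacer,
                    sel.guide.pam,
                    sel.guide.strand,
                    sel.guide.cut_index,
                    round(sel.targeted_mass, 9),
                )
                for sel in lvl.selections
            )
            for lvl in cascade.levels
        ),
        tuple(round(e, 9) for e in rep.retargeting_efficiency_per_level),
        rep.is_recursive,
    )


def _final_verify(contigs: dict, sites) -> None:
    """Re-verify every planted site on the finished genome, with and without
    genome-wide off-target counting; the selected cascade structure must be
    identical so scan records agree with direct per-window designs."""
    from .guides import OfftargetIndex

    index = OfftargetIndex(list(contigs.items()))
    for s in sites:
        seq = contigs[s.contig]
        window = SequenceWindow(s.contig, s.window_start, seq[s.window_start : s.window_end])
        cut_local = s.a_cut - s.window_start
        edit = IndelOutcome(kind="insertion", start=cut_local, length=3, inserted_seq="GAT")
        donor = DonorSpec.from_edit(window.seq, edit)
        plain = run_recursion(window, donor)
        indexed = run_recursion(window, donor, ot_index=index)
        if _cascade_structure(plain) != _cascade_structure(indexed):
            raise GenerationError(
                f"{s.construct} at {s.contig}:{s.a_cut}: off-target counting changes the cascade"
            )
        rep = build_report(indexed)
        if indexed.n_levels != s.expected_levels or rep.is_recursive != s.expected_recursive:
            raise GenerationError(
                f"{s.construct} at {s.contig}:{s.a_cut}: final verification mismatch "
                f"(levels {indexed.n_levels}, recursive {rep.is_recursive})"
            )


def _check_unique_23mers(contigs: dict, sites) -> None:
    """No 23-mer may occur twice anywhere (both strands): guarantees planted
    guides are genome-unique and off-target counts are zero by construction."""
    from .core import revcomp

    seen = {}
    for name, seq in contigs.items():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - 22):
                k = strand_seq[i : i + 23]
                if k in seen and seen[k] != (name, strand_seq is seq, i):
                    # palindromic self-hits aside, duplicates break uniqueness
                    if revcomp(k) != k:
                        raise GenerationError(f"duplicate 23-mer across the genome: {k}")
                seen.setdefault(k, (name, strand_seq is seq, i))
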