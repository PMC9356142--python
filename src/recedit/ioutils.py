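"""File formats, serialization and run configuration.

Reads the standard formats through the usual libraries (FASTA via
Biopython/pyfaidx, GFF3 via gffutils, VCF via cyvcf2) and owns the
package's two output shapes for a designed cascade: a nested JSON tree and
a flat TSV with one row per guide. Both are byte-deterministic for
identical inputs. GFF3/VCF 1-based inclusive coordinates are converted to
internal 0-based half-open at the parser boundary.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .core import DonorSpec, IndelOutcome, SequenceWindow, Substitution
from .guides import FilterConfig
from .predict import PredictorParams
from .search import Cascade, SiteReport, build_report
from .simulate import SimConfig

__all__ = [
    "open_text",
    "read_fasta",
    "write_fasta",
    "cascade_to_dict",
    "cascade_to_json",
    "cascade_to_tsv",
    "report_to_dict",
    "RunConfig",
    "load_config",
    "dump_config",
    "setup_logging",
]

log = logging.getLogger("recedit")

TSV_COLUMNS = [
    "site",
    "level",
    "label",
    "protospacer",
    "pam",
    "strand",
    "cut",
    "on_target",
    "offtarget_hits",
    "targeted_mass",
    "retarget_score",
    "retargeting_efficiency",
]


def open_text(path, mode: str = "rt"):
    """Open a path, transparently decompressing .gz."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict:
    """Contig name -> uppercase sequence, preserving file order (py>=3.7 dicts)."""
    from Bio import SeqIO

    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, contigs: dict, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _round(x: float, nd: int = 10) -> float:
    # fixed rounding keeps JSON/TSV byte-identical across runs
    return round(float(x), nd)


def _outcome_dict(o: IndelOutcome) -> dict:
    return {
        "kind": o.kind,
        "start": o.start,
        "length": o.length,
        "inserted_seq": o.inserted_seq,
        "freq": _round(o.freq),
        "label": o.label,
    }


def _edit_dict(edit) -> dict:
    if isinstance(edit, Substitution):
        return {"kind": "substitution", "position": edit.position, "ref": edit.ref, "alt": edit.alt}
    return _outcome_dict(edit)


def cascade_to_dict(cascade: Cascade, report: SiteReport | None = None) -> dict:
    """Nested, JSON-ready view of a cascade (and optionally its report)."""
    report = report or build_report(cascade)
    doc = {
        "site": {
            "contig": cascade.site.contig_id,
            "start": cascade.site.start,
            "end": cascade.site.end,
            "seq": cascade.site.seq,
        },
        "donor": None
        if cascade.donor is None
        else {
            "edit": _edit_dict(cascade.donor.edit),
            "homology_arm_length": cascade.donor.homology_arm_length,
            "hdr_allele": cascade.donor.hdr_allele,
        },
        "reason": cascade.reason,
        "levels": [],
        "retargeting_efficiency_per_level": [
            _round(e) for e in report.retargeting_efficiency_per_level
        ],
        "is_recursive": report.is_recursive,
        "overall_rank_score": _round(report.overall_rank_score),
    }
    for lvl in cascade.levels:
        doc["levels"].append(
            {
                "indel_mass_total": _round(lvl.indel_mass_total),
                "guides": [
                    {
                        "label": sel.label,
                        "protospacer": sel.guide.protospacer,
                        "pam": sel.guide.pam,
                        "strand": sel.guide.strand,
                        "cut_index": sel.guide.cut_index,
                        "start": sel.guide.start,
                        "on_target": _round(sel.guide.on_target),
                        "offtarget_hits": sel.guide.offtarget_hits,
                        "retarget_score": _round(sel.retarget_score),
                        "targeted_mass": _round(sel.targeted_mass),
                        "targeted_alleles": [
                            {
                                "seq": a.seq,
                                "mass": _round(a.mass),
                                "last_edit": _outcome_dict(a.lineage[-1][1])
                                if a.lineage
                                else None,
                            }
                            for a in sel.targeted_alleles
                        ],
                    }
                    for sel in lvl.selections
                ],
            }
        )
    return doc


def cascade_to_json(cascade: Cascade, report: SiteReport | None = None) -> str:
    return json.dumps(cascade_to_dict(cascade, report), indent=2, sort_keys=True)


def cascade_to_tsv(cascade: Cascade, report: SiteReport | None = None) -> str:
    """Flat one-row-per-guide view; exactly the flattening of the JSON tree."""
    report = report or build_report(cascade)
    site = f"{cascade.site.contig_id}:{cascade.site.start}-{cascade.site.end}"
    effs = report.retargeting_efficiency_per_level
    lines = ["\t".join(TSV_COLUMNS)]
    for li, lvl in enumerate(cascade.levels):
        eff = effs[li] if li < len(effs) else 0.0
        for sel in lvl.selections:
            lines.append(
                "\t".join(
                    str(v)
                    for v in [
                        site,
                        li,
                        sel.label,
                        sel.guide.protospacer,
                        sel.guide.pam,
                        sel.guide.strand,
                        sel.guide.cut_index,
                        _round(sel.guide.on_target),
                        sel.guide.offtarget_hits,
                        _round(sel.targeted_mass),
                        _round(sel.retarget_score),
                        _round(eff),
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def report_to_dict(report: SiteReport) -> dict:
    return cascade_to_dict(report.cascade, report)


@dataclass
class RunConfig:
    """All module configurations under one document.

    Loadable from a YAML file with top-level sections ``predictor``,
    ``filters``, ``search``, ``sim`` and ``scan``; unknown keys anywhere are
    rejected so typos fail loudly.
    """

    predictor: PredictorParams = field(default_factory=PredictorParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    search: "object" = None
    sim: SimConfig = field(default_factory=SimConfig)
    scan: dict = field(default_factory=dict)
    predictor_name: str = "bundled"

    def __post_init__(self) -> None:
        if self.search is None:
            from .search import SearchConfig

            self.search = SearchConfig()

    def digest(self) -> str:
        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:12]


_SECTIONS = {
    "predictor": PredictorParams,
    "filters": FilterConfig,
    "sim": SimConfig,
}


def load_config(path_or_stream) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown sections or keys."""
    from .search import SearchConfig

    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream) or {}
    else:
        with open_text(path_or_stream) as fh:
            doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    sections = dict(_SECTIONS, search=SearchConfig)
    cfg = RunConfig()
    for key, value in doc.items():
        if key == "predictor_name":
            cfg.predictor_name = str(value)
            continue
        if key == "scan":
            cfg.scan = dict(value or {})
            continue
        if key not in sections:
            raise ValueError(f"unknown config section {key!r}")
        cls = sections[key]
        known = {f.name for f in fields(cls)}
        unknown = set(value or {}) - known
        if unknown:
            raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
        setattr(cfg, key, cls(**(value or {})))
    return cfg


def dump_config(cfg: RunConfig) -> str:
    doc = {
        "predictor": asdict(cfg.predictor),
        "filters": asdict(cfg.filters),
        "search": asdict(cfg.search),
        "sim": asdict(cfg.sim),
        "scan": cfg.scan,
        "predictor_name": cfg.predictor_name,
    }
    return yaml.safe_dump(doc, sort_keys=True)


def setup_logging(level: str = "INFO", cfg: RunConfig | None = None, seed: int | None = None) -> None:
    """Configure the package logger with a reproducibility header."""
    from . import __version__

    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    header = f"recedit {__version__}"
    if cfg is not None:
        header += f" config={cfg.digest()}"
    if seed is not None:
        header += f" seed={seed}"
    log.info(header)
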