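"""File input/output: FASTA reference panels, manifest CSVs, reports.

FASTA description lines carry ``taxon=`` and ``marker=`` key-value tags,
e.g. ``>A_rostrata_cytb taxon=A._rostrata marker=cytb`` (spaces in taxon
names are written as underscores and restored on read).
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import BandProfile, DigestResult, Marker, ReferenceSequence
from .classify import SpeciesCall
from .errors import InputError
from .survey import FrequencyEstimate, GlmResult, SampleRecord


def write_fasta(panel: list[ReferenceSequence], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(ref.sequence),
            id=ref.id,
            description=(
                f"taxon={ref.taxon.replace(' ', '_')} marker={ref.marker.value}"
            ),
        )
        for ref in panel
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    panel: list[ReferenceSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            tok.split("=", 1) for tok in rec.description.split() if "=" in tok
        )
        if "taxon" not in tags or "marker" not in tags:
            raise InputError(
                f"FASTA record {rec.id!r} lacks taxon=/marker= tags"
            )
        try:
            marker = Marker(tags["marker"])
        except ValueError as exc:
            raise InputError(f"unknown marker {tags['marker']!r}") from exc
        panel.append(
            ReferenceSequence(
                id=rec.id,
                taxon=tags["taxon"].replace("_", " "),
                marker=marker,
                sequence=str(rec.seq),
            )
        )
    if not panel:
        raise InputError(f"no FASTA records in {path}")
    return panel


MANIFEST_COLUMNS = [
    "sample", "date", "retail_type", "city", "state", "labeled_as",
    "cytb_bands", "s18_bands", "identification", "source_brand",
]


def _parse_bands(cell: str, line_no: int, column: str) -> tuple[int, ...]:
    try:
        bands = tuple(int(b.strip()) for b in cell.split(",") if b.strip())
    except ValueError as exc:
        raise InputError(
            f"line {line_no}: malformed band sizes {cell!r} in {column}"
        ) from exc
    if not bands:
        raise InputError(f"line {line_no}: empty band list in {column}")
    return bands


def read_manifest(path: str | Path, tolerance: float = 0.05) -> list[SampleRecord]:
    """Read a sample manifest CSV (same column layout as the bundled
    survey fixture).  Band cells hold comma-separated sizes in bp."""
    records: list[SampleRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "cytb_bands" not in reader.fieldnames:
            raise InputError(f"{path} is not a manifest CSV (missing header)")
        for line_no, row in enumerate(reader, start=2):
            date = None
            if row.get("date"):
                for fmt in ("%m/%d/%y", "%Y-%m-%d"):
                    try:
                        date = _dt.datetime.strptime(row["date"], fmt).date()
                        break
                    except ValueError:
                        continue
            records.append(
                SampleRecord(
                    sample_id=row["sample"],
                    date=date,
                    retail_type=row["retail_type"],
                    city=row.get("city", ""),
                    state=row["state"],
                    label_text=row.get("labeled_as", ""),
                    cytb_profile=BandProfile(
                        Marker.CYTB,
                        _parse_bands(row["cytb_bands"], line_no, "cytb_bands"),
                        tolerance,
                    ),
                    s18_profile=BandProfile(
                        Marker.S18,
                        _parse_bands(row["s18_bands"], line_no, "s18_bands"),
                        tolerance,
                    ),
                    source_brand=row.get("source_brand", ""),
                )
            )
    if not records:
        raise InputError(f"manifest {path} contains no samples")
    return records


def write_manifest(records: list[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.date.strftime("%m/%d/%y") if r.date else "",
                    r.retail_type,
                    r.city,
                    r.state,
                    r.label_text,
                    ",".join(str(b) for b in r.cytb_profile.bands),
                    ",".join(str(b) for b in r.s18_profile.bands),
                    r.final_call.final.value if r.final_call else "",
                    r.source_brand,
                ]
            )


def write_digest_report(
    results: list[tuple[str, DigestResult]], path: str | Path
) -> None:
    """CSV of per-record digestion outcomes (1-based cut positions)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record", "enzyme", "cut_positions", "fragments", "visible_bands"])
        for rec_id, res in results:
            w.writerow(
                [
                    rec_id,
                    res.enzyme,
                    ";".join(str(p) for p in res.cut_positions),
                    ";".join(str(f) for f in res.fragments),
                    ";".join(str(b) for b in res.visible_bands),
                ]
            )


def write_classification_report(
    records: list[SampleRecord], path: str | Path
) -> None:
    """One row per sample: marker profiles, final call, flags, confirmation."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "sample", "state", "retail_type", "labeled_as",
                "cytb_bands", "s18_bands", "mt_lineage", "nuclear_background",
                "final_call", "flags", "confirmed_taxon", "confirmed_identity",
            ]
        )
        for r in records:
            call = r.final_call
            if call is None:
                raise InputError(f"record {r.sample_id} is not classified")
            w.writerow(
                [
                    r.sample_id,
                    r.state,
                    r.retail_type,
                    r.label_text,
                    ",".join(str(b) for b in r.cytb_profile.bands),
                    ",".join(str(b) for b in r.s18_profile.bands),
                    "|".join(call.mt_lineage),
                    "|".join(call.nuclear_background),
                    call.final.value,
                    "|".join(sorted(call.flags)),
                    call.confirmed_taxon or "",
                    f"{call.confirmed_identity:.4f}" if call.confirmed_identity else "",
                ]
            )


def frequency_to_dict(est: FrequencyEstimate) -> dict:
    return {
        "stratum": est.stratum,
        "k": est.k,
        "n": est.n,
        "p_hat_pct": est.p_hat,
        "sigma_boot_pct": est.sigma_boot,
        "margin_pct": est.margin,
        "ci_pct": list(est.ci),
        "B": est.B,
        "seed": est.seed,
    }


def glm_to_dict(res: GlmResult) -> dict:
    return {
        "predictor": res.predictor,
        "N": res.N,
        "df": res.df,
        "chi_square": round(res.chi_square, 2),
        "p_value": round(res.p_value, 4),
    }


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
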