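"""Readers and writers: NIST-style MSP spectra, template/manifest TSV, MGF.

The MSP dialect is the plain-text NIST layout with one blank line between
records and peak lines ``mz<TAB>intensity<TAB>"annotation"``.  m/z values
are printed with 4 decimals, retention times with 2, intensities as
integers; output is byte-identical across runs for identical inputs.
Reading is lossless for every field the writer emits.
"""

from __future__ import annotations

import csv
from typing import Dict, Iterable, List, Optional, Sequence

from .chem import ChemFormula
from .fragmentation import Peak, PeakAnnotation, SpectrumRecord
from .identification import MatchResult, QueryFeature

__all__ = [
    "write_msp",
    "read_msp",
    "read_mgf_queries",
    "msp_records_to_queries",
    "write_template_tsv",
    "write_manifest_tsv",
    "write_results_tsv",
]

_KNOWN_HEADERS = {
    "NAME",
    "PRECURSORMZ",
    "PRECURSORTYPE",
    "IONMODE",
    "FORMULA",
    "SMILES",
    "RETENTIONTIME",
    "COMMENT",
}


class MSPError(ValueError):
    """Raised on malformed MSP input (with the failing record's index)."""


def _format_comment(comment: Dict[str, str]) -> str:
    return "; ".join(f"{k}={v}" for k, v in comment.items())


def _parse_comment(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
        else:
            out[part] = ""
    return out


def write_msp(records: Sequence[SpectrumRecord], path) -> None:
    """Write records in the MSP dialect (empty input gives an empty file)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, record in enumerate(records):
            if i:
                fh.write("\n")
            fh.write(f"NAME: {record.name}; {record.adduct}\n")
            fh.write(f"PRECURSORMZ: {record.precursor_mz:.4f}\n")
            fh.write(f"PRECURSORTYPE: {record.adduct}\n")
            fh.write(f"IONMODE: {record.polarity.capitalize()}\n")
            if record.formula is not None:
                fh.write(f"FORMULA: {record.formula.hill()}\n")
            if record.smiles:
                fh.write(f"SMILES: {record.smiles}\n")
            if record.rt is not None:
                fh.write(f"RETENTIONTIME: {record.rt:.2f}\n")
            if record.comment:
                fh.write(f"COMMENT: {_format_comment(record.comment)}\n")
            fh.write(f"Num Peaks: {len(record.peaks)}\n")
            for peak in record.peaks:
                line = f"{peak.mz:.4f}\t{peak.intensity:d}"
                if peak.annotation is not None:
                    line += f'\t"{peak.annotation.to_string()}"'
                fh.write(line + "\n")


def read_msp(path) -> List[SpectrumRecord]:
    """Parse an MSP file written by :func:`write_msp` (CRLF tolerated).

    Unknown header fields are preserved in the record's comment map; a
    missing or short peak table raises :class:`MSPError` naming the record.
    """
    records: List[SpectrumRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = [line.rstrip("\r\n") for line in fh]
    i, n = 0, len(lines)
    index = 0
    while i < n:
        while i < n and not lines[i].strip():
            i += 1
        if i >= n:
            break
        headers: Dict[str, str] = {}
        num_peaks: Optional[int] = None
        while i < n and lines[i].strip():
            line = lines[i]
            if ":" not in line:
                raise MSPError(f"record {index}: malformed header line {line!r}")
            key, value = line.split(":", 1)
            key_norm = key.strip().upper().replace(" ", "")
            if key_norm == "NUMPEAKS":
                num_peaks = int(value.strip())
                i += 1
                break
            headers[key.strip()] = value.strip()
            i += 1
        if num_peaks is None:
            raise MSPError(f"record {index}: missing 'Num Peaks' line")
        peaks: List[Peak] = []
        for _ in range(num_peaks):
            if i >= n or not lines[i].strip():
                raise MSPError(
                    f"record {index}: expected {num_peaks} peaks, got {len(peaks)}"
                )
            fields = lines[i].split("\t")
            if len(fields) < 2:
                raise MSPError(f"record {index}: malformed peak line {lines[i]!r}")
            annotation = None
            if len(fields) >= 3:
                text = fields[2].strip().strip('"')
                if text:
                    annotation = PeakAnnotation.from_string(text)
            peaks.append(
                Peak(mz=float(fields[0]), intensity=int(round(float(fields[1]))),
                     annotation=annotation)
            )
            i += 1
        if i < n and lines[i].strip():
            raise MSPError(
                f"record {index}: more peak lines than Num Peaks ({num_peaks})"
            )

        comment = _parse_comment(headers.get("COMMENT", ""))
        for key, value in headers.items():
            if key.upper().replace(" ", "") not in _KNOWN_HEADERS:
                comment[key] = value
        name_field = headers.get("NAME", "")
        adduct = headers.get("PRECURSORTYPE", "")
        name = name_field
        suffix = f"; {adduct}"
        if adduct and name_field.endswith(suffix):
            name = name_field[: -len(suffix)]
        formula = headers.get("FORMULA")
        rt = headers.get("RETENTIONTIME")
        records.append(
            SpectrumRecord(
                name=name,
                class_code=name.split(" ")[0] if name else "",
                adduct=adduct,
                polarity=headers.get("IONMODE", "").strip().lower(),
                precursor_mz=float(headers.get("PRECURSORMZ", "nan")),
                peaks=peaks,
                formula=ChemFormula.parse(formula) if formula else None,
                smiles=headers.get("SMILES") or None,
                rt=float(rt) if rt else None,
                comment=comment,
            )
        )
        index += 1
    return records


def read_mgf_queries(path) -> List[QueryFeature]:
    """Read query peak lists from a Mascot generic format file."""
    from pyteomics import mgf

    queries: List[QueryFeature] = []
    with mgf.MGF(str(path)) as reader:
        for i, spectrum in enumerate(reader):
            params = spectrum.get("params", {})
            pepmass = params.get("pepmass", (float("nan"),))
            charge = params.get("charge")
            polarity = "negative"
            if charge:
                polarity = "negative" if int(charge[0]) < 0 else "positive"
            queries.append(
                QueryFeature(
                    id=str(params.get("title", f"query-{i}")),
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    rt=(float(params["rtinseconds"]) / 60.0
                        if "rtinseconds" in params else None),
                    peaks=list(
                        zip(
                            (float(x) for x in spectrum["m/z array"]),
                            (float(x) for x in spectrum["intensity array"]),
                        )
                    ),
                )
            )
    return queries


def msp_records_to_queries(records: Iterable[SpectrumRecord]) -> List[QueryFeature]:
    """Treat library-format MSP records as query features (self-search etc.)."""
    return [
        QueryFeature(
            id=r.record_id,
            precursor_mz=r.precursor_mz,
            polarity=r.polarity,
            rt=r.rt,
            peaks=[(p.mz, float(p.intensity)) for p in r.peaks],
        )
        for r in records
    ]


def write_template_tsv(records: Sequence[SpectrumRecord], path) -> None:
    """One row per record with a semicolon-joined fragment column
    (``mz:intensity:label`` entries)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["name", "class", "adduct", "precursor_mz", "formula", "smiles",
             "rt", "fragments"]
        )
        for record in records:
            fragments = ";".join(
                f"{p.mz:.4f}:{p.intensity}:"
                f"{p.annotation.label if p.annotation else ''}"
                for p in record.peaks
            )
            writer.writerow(
                [
                    record.name,
                    record.class_code,
                    record.adduct,
                    f"{record.precursor_mz:.4f}",
                    record.formula.hill() if record.formula else "",
                    record.smiles or "",
                    f"{record.rt:.2f}" if record.rt is not None else "",
                    fragments,
                ]
            )


def write_manifest_tsv(manifest, path) -> None:
    """Write a per-class manifest DataFrame as TSV."""
    manifest.to_csv(path, sep="\t", index=False)


def write_results_tsv(results_by_query: Dict[str, List[MatchResult]], path) -> None:
    """Identification results, one row per (query, candidate)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["query_id", "record_id", "class", "name", "dot_product",
             "reverse_dot_product", "matched_fraction", "precursor_error_da",
             "rt_error_min", "total_score", "accepted"]
        )
        for query_id, results in results_by_query.items():
            for r in results:
                writer.writerow(
                    [
                        query_id,
                        r.record_id,
                        r.class_code,
                        r.name,
                        f"{r.dot_product:.2f}",
                        f"{r.reverse_dot_product:.2f}",
                        f"{r.matched_fraction:.4f}",
                        f"{r.precursor_error:.5f}",
                        f"{r.rt_error:.3f}" if r.rt_error is not None else "",
                        f"{r.total_score:.2f}",
                        str(r.accepted).lower(),
                    ]
                )
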