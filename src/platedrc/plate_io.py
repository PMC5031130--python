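"""Readers and writers for plate-map and kinetic-export files.

Three text formats are supported, all documented here and written by this
module so that every pipeline stage can run from files on disk:

* **Plate-map XML** — root ``<platemap id=...>`` with one
  ``<well row="B" col="2">`` element per well; children ``<compound name=...
  conc=... units=.../>``, ``<growthcondition name=.../>`` and
  ``<celltype name=... passage=... seeding=.../>``; vehicle wells carry
  ``control="true"``.
* **Plate-map table** — tab-delimited with header
  ``row col sampleid conc units growthcondition celltype passage
  seedingdensity samptype``.
* **Kinetic export** — tab-delimited matrix: comment/metadata lines prefixed
  ``#``, then a header row ``Elapsed`` followed by well labels (``B2``...),
  then one numeric row per timepoint.  Elapsed time is in hours and is the
  single time authority; any ``Date Time`` column is ignored.

Decimal points only: files with comma decimals are rejected, never silently
misread.  Missing numeric cells are an error, not imputed.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from lxml import etree

from .errors import PlateParseError, PlateValidationError
from .plate import PlateData, PlateMap, SampleType, WellAddress, WellAnnotation

PathLike = Union[str, Path]

#: Units strings accepted without comment; anything else triggers a warning
#: but is kept verbatim.
KNOWN_UNITS = {"", "M", "mM", "uM", "µM", "nM", "pM", "ug/ml", "ng/ml", "mg/ml", "%"}

TABLE_COLUMNS = [
    "row",
    "col",
    "sampleid",
    "conc",
    "units",
    "growthcondition",
    "celltype",
    "passage",
    "seedingdensity",
    "samptype",
]


def _parse_float(text: str, context: str) -> float:
    text = text.strip()
    if "," in text:
        raise PlateParseError(
            f"{context}: comma decimal {text!r} rejected (decimal points only)"
        )
    try:
        return float(text)
    except ValueError as exc:
        raise PlateParseError(f"{context}: non-numeric value {text!r}") from exc


def _check_units(units: str, context: str) -> str:
    if units not in KNOWN_UNITS:
        warnings.warn(f"{context}: unrecognised units string {units!r} kept verbatim")
    return units


# ---------------------------------------------------------------------------
# plate-map XML
# ---------------------------------------------------------------------------

def import_platemap_xml(path: PathLike) -> PlateMap:
    """Read a plate-map XML file into a :class:`PlateMap`.

    Wells flagged ``control="true"`` become vehicle controls; wells with a
    ``<compound>`` child carrying a positive concentration become compound
    wells; anything else is a blank.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PlateParseError(f"{path}: malformed XML at line {exc.lineno}: {exc.msg}") from exc
    root = tree.getroot()
    if root.tag != "platemap":
        raise PlateParseError(f"{path}: expected root <platemap>, found <{root.tag}>")
    plate_id = root.get("id", path.stem)
    wells = []
    for el in root.iterfind("well"):
        addr = WellAddress(el.get("row", "").upper(), int(el.get("col", "0")))
        is_control = el.get("control", "false").lower() == "true"
        comp = el.find("compound")
        gc = el.find("growthcondition")
        ct = el.find("celltype")
        name = comp.get("name", "") if comp is not None else ""
        conc = (
            _parse_float(comp.get("conc", "0"), f"{path} well {addr}")
            if comp is not None
            else 0.0
        )
        units = _check_units(comp.get("units", "") if comp is not None else "", f"well {addr}")
        if is_control:
            stype = SampleType.VEHICLE_CONTROL
        elif name and conc > 0:
            stype = SampleType.COMPOUND
        else:
            stype = SampleType.BLANK
        wells.append(
            WellAnnotation(
                address=addr,
                sample_type=stype,
                compound_name=name,
                concentration=conc,
                concentration_units=units,
                growth_condition=gc.get("name", "") if gc is not None else "",
                cell_type=ct.get("name", "") if ct is not None else "",
                passage=ct.get("passage", "") if ct is not None else "",
                seeding_density=(
                    _parse_float(ct.get("seeding", "0"), f"{path} well {addr}")
                    if ct is not None
                    else 0.0
                ),
            )
        )
    return PlateMap(plate_id, wells)


def export_platemap_xml(platemap: PlateMap, path: PathLike) -> None:
    """Write a :class:`PlateMap` in the XML dialect read by
    :func:`import_platemap_xml` (lossless round-trip)."""
    root = etree.Element("platemap", id=platemap.plate_id)
    for w in platemap.wells:
        el = etree.SubElement(root, "well", row=w.address.row, col=str(w.address.column))
        if w.sample_type is SampleType.VEHICLE_CONTROL:
            el.set("control", "true")
        if w.compound_name or w.concentration or w.concentration_units:
            etree.SubElement(
                el,
                "compound",
                name=w.compound_name,
                conc=repr(float(w.concentration)),
                units=w.concentration_units,
            )
        if w.growth_condition:
            etree.SubElement(el, "growthcondition", name=w.growth_condition)
        if w.cell_type or w.passage or w.seeding_density:
            etree.SubElement(
                el,
                "celltype",
                name=w.cell_type,
                passage=w.passage,
                seeding=repr(float(w.seeding_density)),
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# plate-map table
# ---------------------------------------------------------------------------

def import_platemap_table(path: PathLike) -> PlateMap:
    """Read a tab-delimited plate map (same semantics as the XML reader)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    plate_id = path.stem
    body = []
    for ln in text.splitlines():
        if ln.startswith("#"):
            key, _, val = ln[1:].strip().partition("=")
            if key.strip() == "plate_id" and val:
                plate_id = val.strip()
            continue
        body.append(ln)
    df = pd.read_csv(
        io.StringIO("\n".join(body)), sep="\t", dtype=str, keep_default_na=False
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateParseError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise PlateValidationError(f"{path}: no wells")
    wells = []
    for i, rec in df.iterrows():
        ctx = f"{path} row {i + 2}"  # +2: header line + 1-based
        try:
            stype = SampleType(rec["samptype"].strip())
        except ValueError as exc:
            raise PlateParseError(f"{ctx}: unknown samptype {rec['samptype']!r}") from exc
        wells.append(
            WellAnnotation(
                address=WellAddress(rec["row"].strip().upper(), int(rec["col"])),
                sample_type=stype,
                compound_name=rec["sampleid"].strip(),
                concentration=_parse_float(rec["conc"] or "0", ctx),
                concentration_units=_check_units(rec["units"].strip(), ctx),
                growth_condition=rec["growthcondition"].strip(),
                cell_type=rec["celltype"].strip(),
                passage=rec["passage"].strip(),
                seeding_density=_parse_float(rec["seedingdensity"] or "0", ctx),
            )
        )
    return PlateMap(plate_id, wells)


def export_platemap_table(platemap: PlateMap, path: PathLike) -> None:
    lines = [f"# plate_id={platemap.plate_id}", "\t".join(TABLE_COLUMNS)]
    for w in platemap.wells:
        lines.append(
            "\t".join(
                [
                    w.address.row,
                    str(w.address.column),
                    w.compound_name,
                    repr(float(w.concentration)),
                    w.concentration_units,
                    w.growth_condition,
                    w.cell_type,
                    w.passage,
                    repr(float(w.seeding_density)),
                    w.sample_type.value,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# kinetic plate data
# ---------------------------------------------------------------------------

def import_plate_data(path: PathLike, metric: str | None = None) -> PlateData:
    """Read a kinetic plate export into long-format :class:`PlateData`.

    The reader tolerates a UTF-8 BOM, Windows line endings, ``#``-prefixed
    metadata lines and a ``Date Time`` column (ignored: elapsed hours is the
    time authority).  The growth-metric name comes from the ``metric``
    argument; if omitted it is taken from a ``# metric=...`` metadata line,
    falling back to ``"percent confluence"``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    plate_id = path.stem
    file_metric = None
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln[1:].split("\t"):
                key, _, val = tok.strip().partition("=")
                if key == "plate_id" and val:
                    plate_id = val
                elif key == "metric" and val:
                    file_metric = val
    metric = metric or file_metric or "percent confluence"
    header_idx = None
    for i, ln in enumerate(lines[:6]):
        if ln.startswith("#"):
            continue
        fields = [f.strip() for f in ln.split("\t")]
        if any(f.lower() == "elapsed" for f in fields):
            header_idx = i
            break
    if header_idx is None:
        raise PlateParseError(f"{path}: no header row with an 'Elapsed' column found")
    header = [f.strip() for f in lines[header_idx].split("\t")]
    lower = [h.lower() for h in header]
    elapsed_col = lower.index("elapsed")
    skip_cols = {i for i, h in enumerate(lower) if h in ("date time", "datetime", "date")}
    well_cols = [
        (i, WellAddress.from_label(h))
        for i, h in enumerate(header)
        if i != elapsed_col and i not in skip_cols
    ]
    if not well_cols:
        raise PlateParseError(f"{path}: header contains no well labels")
    records = []
    for ln in lines[header_idx + 1 :]:
        if ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise PlateParseError(
                f"{path}: non-rectangular export (row with {len(fields)} fields, "
                f"header has {len(header)})"
            )
        t = _parse_float(fields[elapsed_col], f"{path} elapsed time")
        if t < 0:
            raise PlateParseError(f"{path}: negative elapsed time {t}")
        for i, addr in well_cols:
            if fields[i].strip() == "":
                raise PlateParseError(
                    f"{path}: missing value for well {addr} at {t} h (not imputed)"
                )
            records.append((addr, t, _parse_float(fields[i], f"{path} well {addr}")))
    if not records:
        raise PlateValidationError(f"{path}: no data rows")
    return PlateData.from_records(plate_id, metric, records)


def export_plate_data(platedata: PlateData, path: PathLike) -> None:
    """Write :class:`PlateData` as a kinetic export (lossless round-trip)."""
    addrs = sorted(platedata.addresses)
    times = platedata.timepoints
    wide = platedata.df.pivot_table(
        index="elapsed_h", columns=["row", "col"], values="value"
    )
    lines = [f"# plate_id={platedata.plate_id}\tmetric={platedata.metric}"]
    lines.append("\t".join(["Elapsed"] + [a.label for a in addrs]))
    for t in times:
        row = [repr(float(t))]
        for a in addrs:
            v = wide.loc[t, (a.row, a.column)]
            if pd.isna(v):
                raise PlateValidationError(f"missing value for well {a} at {t} h")
            row.append(repr(float(v)))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
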