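"""Table readers/writers, TraML anchor export, and pipeline configuration.

TSV is the canonical interchange format, with OpenSWATH-style column names
for the assay library.  Floating-point columns are written with 17
significant digits so every table round-trips exactly.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import chem
from .glycan import DEFAULT_REGISTRY, GlycanComposition, GlycanStruct, parse_glycan
from .library import AnnotatedTransition, IsolationScheme, LibraryEntry, PrecursorId

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "library_to_table",
    "table_to_library",
    "write_library",
    "read_library",
    "write_table",
    "read_feature_table",
    "export_anchors_traml",
    "read_glycan_db",
    "write_glycan_db",
]

FLOAT_FORMAT = "%.17g"

LIBRARY_COLUMNS = [
    "PeptideSequence", "Modifications", "GlycanStructure", "GlycanComposition",
    "PrecursorCharge", "PrecursorMz", "NormalizedRetentionTime",
    "ProductMz", "LibraryIntensity", "FragmentType", "FragmentSeriesNumber",
    "FragmentGlycanComposition", "FragmentCharge", "IsQuantifier",
    "IsDecoy", "DecoyType", "ReplicateCount", "Provenance",
]

FEATURE_REQUIRED = ["run_id", "precursor_id", "peak_group_id", "rt", "label"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _mods_to_text(mods: Sequence[chem.Modification]) -> str:
    return ";".join(f"{name}@{pos}:{delta:.5f}" for name, pos, delta in mods)


def _mods_from_text(text: str) -> Tuple[chem.Modification, ...]:
    if not text or text != text:  # empty or NaN
        return ()
    out = []
    for item in str(text).split(";"):
        name, rest = item.split("@")
        pos, delta = rest.split(":")
        out.append((name, int(pos), float(delta)))
    return tuple(out)


def library_to_table(entries: Sequence[LibraryEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        pid = e.precursor_id
        for t in e.transitions:
            rows.append({
                "PeptideSequence": pid.peptide,
                "Modifications": _mods_to_text(pid.modifications),
                "GlycanStructure": e.glycan_struct.canonical_text if e.glycan_struct else "",
                "GlycanComposition": str(pid.glycan_composition),
                "PrecursorCharge": pid.charge,
                "PrecursorMz": e.precursor_mz,
                "NormalizedRetentionTime": e.rt,
                "ProductMz": t.mz,
                "LibraryIntensity": t.intensity,
                "FragmentType": t.series,
                "FragmentSeriesNumber": "" if t.ordinal is None else t.ordinal,
                "FragmentGlycanComposition": "" if t.composition is None else t.composition,
                "FragmentCharge": t.charge,
                "IsQuantifier": int(t.quantify),
                "IsDecoy": int(e.is_decoy),
                "DecoyType": e.decoy_type,
                "ReplicateCount": e.replicate_count,
                "Provenance": yaml.safe_dump(e.provenance, default_flow_style=True).strip()
                if e.provenance else "",
            })
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def table_to_library(df: pd.DataFrame) -> List[LibraryEntry]:
    missing = [c for c in LIBRARY_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise SchemaError(f"library table is missing column(s): {', '.join(missing)}")
    entries: List[LibraryEntry] = []
    group_cols = ["PeptideSequence", "Modifications", "GlycanComposition",
                  "PrecursorCharge", "IsDecoy", "DecoyType"]
    df = df.fillna({"Modifications": "", "FragmentGlycanComposition": "",
                    "GlycanStructure": "", "DecoyType": "", "Provenance": ""})
    for keys, sub in df.groupby(group_cols, sort=False, dropna=False):
        peptide, mods_text, comp_text, charge, is_decoy, decoy_type = keys
        transitions = []
        for _, r in sub.iterrows():
            ordinal = r.get("FragmentSeriesNumber", "")
            comp = r.get("FragmentGlycanComposition", "")
            transitions.append(AnnotatedTransition(
                series=str(r["FragmentType"]),
                ordinal=int(ordinal) if str(ordinal) not in ("", "nan") else None,
                composition=str(comp) if str(r["FragmentType"]) == "Y" else None,
                charge=int(r["FragmentCharge"]),
                mz=float(r["ProductMz"]),
                intensity=float(r["LibraryIntensity"]),
                quantify=bool(int(r.get("IsQuantifier", 0))),
            ))
        transitions.sort(key=lambda t: t.mz)
        first = sub.iloc[0]
        struct_text = str(first["GlycanStructure"])
        prov_text = str(first.get("Provenance", "") or "")
        entries.append(LibraryEntry(
            precursor_id=PrecursorId(
                str(peptide), _mods_from_text(mods_text),
                GlycanComposition.parse(str(comp_text)), int(charge),
            ),
            glycan_struct=parse_glycan(struct_text) if struct_text else None,
            precursor_mz=float(first["PrecursorMz"]),
            rt=float(first["NormalizedRetentionTime"]),
            transitions=transitions,
            replicate_count=int(first.get("ReplicateCount", 1)),
            is_decoy=bool(int(is_decoy)),
            decoy_type=str(decoy_type),
            provenance=yaml.safe_load(prov_text) if prov_text else {},
        ))
    return entries


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_library(entries: Sequence[LibraryEntry], path) -> None:
    write_table(library_to_table(entries), path)


def read_library(path) -> List[LibraryEntry]:
    return table_to_library(
        pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""],
                    float_precision="round_trip")
    )


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in FEATURE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s): {', '.join(missing)}")
    if not any(c.startswith("pep_") for c in df.columns):
        raise SchemaError("feature table has no pep_* sub-score columns")
    if not any(c.startswith("gly_") for c in df.columns):
        raise SchemaError("feature table has no gly_* sub-score columns")
    return df


def export_anchors_traml(anchors: Sequence[LibraryEntry], path) -> None:
    """Export anchor glycopeptides as a TraML transition list.

    One <Peptide> per anchor precursor (retention time attached) and one
    <Transition> per library transition, following the controlled-vocabulary
    skeleton of the PSI TraML 1.0 schema.
    """
    NS = "http://psi.hupo.org/ms/traml"
    ET.register_namespace("", NS)
    root = ET.Element(f"{{{NS}}}TraML", version="1.0.0")
    compounds = ET.SubElement(root, f"{{{NS}}}CompoundList")
    transitions = ET.SubElement(root, f"{{{NS}}}TransitionList")
    for e in anchors:
        pid = e.precursor_id
        pep_id = f"{pid.peptide}_{pid.glycan_composition}_{pid.charge}"
        pep = ET.SubElement(compounds, f"{{{NS}}}Peptide",
                            id=pep_id, sequence=pid.peptide.replace("J", "N"))
        rt_list = ET.SubElement(pep, f"{{{NS}}}RetentionTimeList")
        rt_el = ET.SubElement(rt_list, f"{{{NS}}}RetentionTime")
        ET.SubElement(rt_el, f"{{{NS}}}cvParam", cvRef="MS", accession="MS:1000896",
                      name="normalized retention time", value=f"{e.rt:.6f}")
        for i, t in enumerate(e.transitions):
            tr = ET.SubElement(transitions, f"{{{NS}}}Transition",
                               id=f"{pep_id}_t{i}", peptideRef=pep_id)
            prec = ET.SubElement(tr, f"{{{NS}}}Precursor")
            ET.SubElement(prec, f"{{{NS}}}cvParam", cvRef="MS", accession="MS:1000827",
                          name="isolation window target m/z",
                          value=f"{e.precursor_mz:.6f}")
            prod = ET.SubElement(tr, f"{{{NS}}}Product")
            ET.SubElement(prod, f"{{{NS}}}cvParam", cvRef="MS", accession="MS:1000827",
                          name="isolation window target m/z", value=f"{t.mz:.6f}")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_glycan_db(path) -> List[GlycanStruct]:
    """Glycan database: one canonical structure string per line (TSV; first
    column is the structure, further columns are ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(parse_glycan(line.split("\t")[0]))
    return out


def write_glycan_db(structs: Sequence[GlycanStruct], path) -> None:
    lines = [f"{s.canonical_text}\t{s.composition()}" for s in structs]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineConfig:
    """Tolerances, isolation scheme, thresholds and seeds for the pipeline."""

    ms1_tol_ppm: float = 10.0
    ms2_tol_ppm: float = 20.0
    window_first_center: float = 700.0
    n_windows: int = 40
    window_width: float = 25.0
    window_overlap: float = 1.0
    scan_range: Tuple[float, float] = (200.0, 2000.0)
    run_q: float = 0.05
    best_run_q: float = 0.01
    global_q: float = 0.01
    glycoform_run_q: float = 0.05
    glycoform_best_run_q: float = 0.01
    knn_k: int = 3
    n_bg: int = 50
    seed: int = 1
    cross_ring_offset: float = chem.CROSS_RING_OFFSET

    def __post_init__(self) -> None:
        for name in ("run_q", "best_run_q", "global_q",
                     "glycoform_run_q", "glycoform_best_run_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    def isolation_scheme(self) -> IsolationScheme:
        return IsolationScheme.uniform(
            self.window_first_center, self.n_windows,
            self.window_width, self.window_overlap,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "scan_range" in data:
            data["scan_range"] = tuple(data["scan_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.__dict__, sort_keys=True, default_flow_style=True).encode()
        ).hexdigest()[:12]
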