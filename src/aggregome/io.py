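"""Readers, writers and containers for the pipeline's external inputs.

The quantitative starting point is a MaxQuant-style ``proteinGroups.txt``
table: one row per protein group, label-free quantification (LFQ) intensity
columns per sample, and ``+`` flags marking potential contaminants and
reversed (decoy) sequences.  LFQ intensities of exactly zero denote
non-detection and are stored as missing, never as true zeros.

Auxiliary inputs are gene-set collections (GMT or two-column TSV, optionally
with a per-member evidence count), protein sequences (FASTA), gene-level
count matrices (TSV) and per-protein score tables (TANGO, CamSol,
catGRANULE, PScore, NSAF or similar, as TSV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

#: Score names accepted in score tables.  ``tango``/``camsol`` are intrinsic
#: aggregation predictors, ``catgranule``/``pscore`` LLPS predictors, ``nsaf``
#: a spectral-count abundance measure.
SCORE_REGISTRY = frozenset(
    {"tango", "camsol", "catgranule", "pscore", "nsaf", "builtin_agg", "builtin_llps"}
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

CONDITION_CASE = "case"
CONDITION_CONTROL = "control"
FRACTION_AGGREGATE = "aggregate"
FRACTION_WCL = "wcl"


@dataclass(frozen=True)
class SampleInfo:
    """Design entry for one intensity column."""

    label: str
    condition: str  # "case" (treated) or "control"
    replicate: int
    fraction: str = FRACTION_AGGREGATE  # "aggregate" or "wcl"
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.condition not in (CONDITION_CASE, CONDITION_CONTROL):
            raise DesignError(f"unknown condition {self.condition!r}")
        if self.fraction not in (FRACTION_AGGREGATE, FRACTION_WCL):
            raise DesignError(f"unknown fraction {self.fraction!r}")
        if self.replicate < 1:
            raise DesignError("replicate_index must be a positive integer")


class SampleDesign:
    """Immutable collection of :class:`SampleInfo` with unique labels."""

    def __init__(self, samples: Sequence[SampleInfo]):
        labels = [s.label for s in samples]
        if len(set(labels)) != len(labels):
            raise DesignError("sample labels must be unique")
        self._samples = tuple(samples)

    def __iter__(self):
        return iter(self._samples)

    def __len__(self) -> int:
        return len(self._samples)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleDesign) and self._samples == other._samples

    @property
    def samples(self) -> tuple[SampleInfo, ...]:
        return self._samples

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self._samples]

    def labels_for(self, condition: str | None = None, fraction: str | None = None) -> list[str]:
        out = []
        for s in self._samples:
            if condition is not None and s.condition != condition:
                continue
            if fraction is not None and s.fraction != fraction:
                continue
            out.append(s.label)
        return out

    @property
    def case_labels(self) -> list[str]:
        return self.labels_for(condition=CONDITION_CASE)

    @property
    def control_labels(self) -> list[str]:
        return self.labels_for(condition=CONDITION_CONTROL)

    def subset(self, fraction: str) -> "SampleDesign":
        kept = [s for s in self._samples if s.fraction == fraction]
        if not kept:
            raise DesignError(f"no samples with fraction {fraction!r}")
        return SampleDesign(kept)

    def require_replicates(self, minimum: int = 2) -> None:
        """Raise unless every (condition, fraction) present has >= minimum replicates."""
        counts: dict[tuple[str, str], int] = {}
        for s in self._samples:
            counts[(s.condition, s.fraction)] = counts.get((s.condition, s.fraction), 0) + 1
        for key, n in counts.items():
            if n < minimum:
                raise DesignError(f"condition/fraction {key} has {n} replicates (< {minimum})")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        required = {"label", "condition", "replicate", "fraction"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        samples = [
            SampleInfo(
                label=str(r.label),
                condition=str(r.condition),
                replicate=int(r.replicate),
                fraction=str(r.fraction),
                cell_line=str(getattr(r, "cell_line", "") or ""),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [s.label for s in self._samples],
                "condition": [s.condition for s in self._samples],
                "replicate": [s.replicate for s in self._samples],
                "fraction": [s.fraction for s in self._samples],
                "cell_line": [s.cell_line for s in self._samples],
            }
        )


def read_sample_design(path: str | Path) -> SampleDesign:
    return SampleDesign.from_frame(pd.read_csv(path, sep="\t"))


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ProteinGroupTable:
    """Protein-group rows with per-sample linear-scale LFQ intensities.

    ``meta`` is indexed by the full (semicolon-separated) majority-protein id
    and carries gene symbols, flags and peptide counts; ``intensities`` shares
    the index, one column per sample label, ``NaN`` marking non-detection.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise FormatError("meta and intensity tables must share their index")
        if self.intensities.columns.duplicated().any():
            raise FormatError("duplicate sample columns in intensity table")
        values = self.intensities.to_numpy(dtype=float)
        if np.any(values[np.isfinite(values)] < 0):
            raise FormatError("negative LFQ intensity encountered")
        if np.any(values == 0):
            raise FormatError("zero LFQ intensity encountered; zeros must be stored as missing")

    @property
    def group_ids(self) -> pd.Index:
        return self.meta.index

    def primary_ids(self) -> pd.Index:
        """First accession of each majority-protein id list."""
        return pd.Index([gid.split(";")[0].strip() for gid in self.meta.index], name="id")

    def __len__(self) -> int:
        return len(self.meta)


_MQ_REQUIRED = ["Majority protein IDs", "Gene names", "Potential contaminant", "Reverse"]


def read_protein_groups(path: str | Path, design: SampleDesign) -> ProteinGroupTable:
    """Read a MaxQuant-dialect proteinGroups table against a sample design.

    Raises :class:`FormatError` for a missing required column or duplicated
    sample column, :class:`DesignError` for a design label with no matching
    ``LFQ intensity <label>`` column.  Intensities of 0 become missing.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise FormatError(f"duplicated column(s) in {path.name}: {sorted(dupes)}")

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MQ_REQUIRED:
        if col not in frame.columns:
            raise FormatError(f"required column {col!r} missing from {path.name}")

    lfq_cols = {}
    for label in design.labels:
        col = f"LFQ intensity {label}"
        if col not in frame.columns:
            raise DesignError(f"design label {label!r} has no column {col!r} in {path.name}")
        lfq_cols[label] = col

    ids = frame["Majority protein IDs"].str.strip()
    if ids.duplicated().any():
        raise FormatError("duplicate protein-group identifiers")

    meta = pd.DataFrame(index=pd.Index(ids, name="group_id"))
    meta["gene_symbols"] = [
        tuple(g.strip() for g in cell.split(";") if g.strip())
        for cell in frame["Gene names"]
    ]
    meta["is_contaminant"] = (frame["Potential contaminant"].str.strip() == "+").to_numpy()
    meta["is_reverse"] = (frame["Reverse"].str.strip() == "+").to_numpy()
    if "Razor + unique peptides" in frame.columns:
        meta["razor_unique_peptides"] = (
            pd.to_numeric(frame["Razor + unique peptides"], errors="coerce")
            .fillna(0)
            .astype(int)
            .to_numpy()
        )
    else:
        meta["razor_unique_peptides"] = 0

    intensities = pd.DataFrame(index=meta.index)
    for label, col in lfq_cols.items():
        vals = pd.to_numeric(frame[col].replace("", np.nan), errors="raise").astype(float)
        vals = vals.mask(vals == 0)  # MaxQuant zeros are non-detections
        intensities[label] = vals.to_numpy()
    return ProteinGroupTable(meta=meta, intensities=intensities)


def write_protein_groups(table: ProteinGroupTable, path: str | Path) -> None:
    """Write back in the MaxQuant dialect (missing values as 0)."""
    out = pd.DataFrame()
    out["Majority protein IDs"] = table.meta.index
    out["Gene names"] = [";".join(g) for g in table.meta["gene_symbols"]]
    out["Razor + unique peptides"] = table.meta["razor_unique_peptides"].to_numpy()
    out["Potential contaminant"] = np.where(table.meta["is_contaminant"], "+", "")
    out["Reverse"] = np.where(table.meta["is_reverse"], "+", "")
    for label in table.intensities.columns:
        out[f"LFQ intensity {label}"] = table.intensities[label].fillna(0).to_numpy()
    out.to_csv(path, sep="\t", index=False)


def filter_contaminants_reverse(table: ProteinGroupTable) -> ProteinGroupTable:
    """Drop rows flagged as potential contaminant or reversed decoy."""
    flagged = table.meta["is_contaminant"] | table.meta["is_reverse"]
    n_removed = int(flagged.sum())
    if n_removed:
        logger.info("filtered %d contaminant/reverse protein groups", n_removed)
    keep = ~flagged
    return ProteinGroupTable(meta=table.meta.loc[keep].copy(), intensities=table.intensities.loc[keep].copy())


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]
    provenance: str = ""


class GeneSetCollection(Mapping[str, GeneSet]):
    """Named, deduplicated identifier sets."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise FormatError(f"duplicate gene-set name {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def members(self, name: str) -> frozenset[str]:
        return self._sets[name].members


def read_gene_sets(path: str | Path, min_evidence: int | None = None) -> GeneSetCollection:
    """Read gene sets from GMT or two/three-column TSV.

    The TSV dialect has a header with columns ``set``, ``member`` and an
    optional ``evidence`` integer column; members with evidence below
    ``min_evidence`` are excluded (e.g. chaperone clients seen in fewer than
    two of three pull-down repeats).  GMT rows carry no evidence counts.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n").split("\t")
    is_tsv = first and first[0].strip().lower() == "set"
    sets: dict[str, set[str]] = {}
    prov: dict[str, str] = {}
    if is_tsv:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if "member" not in frame.columns:
            raise FormatError("two-column gene-set table needs 'set' and 'member' columns")
        has_ev = "evidence" in frame.columns
        for row in frame.itertuples(index=False):
            name = str(row.set).strip()
            member = str(row.member).strip()
            if not member:
                continue
            if has_ev and min_evidence is not None:
                ev = int(row.evidence)
                if ev < min_evidence:
                    continue
            sets.setdefault(name, set()).add(member)
            prov.setdefault(name, str(path))
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    raise FormatError("GMT rows need >= 3 tab-separated fields")
                name, description = fields[0].strip(), fields[1].strip()
                members = {f.strip() for f in fields[2:] if f.strip()}
                sets.setdefault(name, set()).update(members)
                prov.setdefault(name, description or str(path))
    out = []
    for name, members in sets.items():
        if not members:
            warnings.warn(f"gene set {name!r} is empty after filtering", stacklevel=2)
        out.append(GeneSet(name=name, members=frozenset(members), provenance=prov.get(name, "")))
    return GeneSetCollection(out)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            gs = collection[name]
            fh.write("\t".join([gs.name, gs.provenance or "na", *sorted(gs.members)]) + "\n")


class MappedIds(NamedTuple):
    ids: frozenset[str]
    n_unmapped: int


def map_identifiers(ids: Iterable[str], mapping: Mapping[str, str] | None = None) -> MappedIds:
    """Reconcile identifiers against an (optionally partial) mapping.

    Semicolon-separated protein-group ids are resolved to the first accession
    before lookup.  Matching is exact first, then case-insensitive (gene
    symbols).  Unmapped ids pass through unchanged and are counted.
    """
    mapping = mapping or {}
    folded = {k.strip().casefold(): v for k, v in mapping.items()}
    out: set[str] = set()
    n_unmapped = 0
    for raw in ids:
        key = str(raw).split(";")[0].strip()
        if key in mapping:
            out.add(mapping[key])
        elif key.casefold() in folded:
            out.add(folded[key.casefold()])
        else:
            if mapping:
                n_unmapped += 1
            out.add(key)
    return MappedIds(frozenset(out), n_unmapped)


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {identifier: amino-acid sequence}.

    Residues outside the 20-letter alphabet (plus X) are mapped to ``X`` with
    a warning; empty sequences and duplicate identifiers are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate sequence identifier {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {record.id!r}")
        if any(ch not in _VALID_RESIDUES for ch in seq):
            warnings.warn(f"invalid residues in {record.id!r} mapped to X", stacklevel=2)
            seq = "".join(ch if ch in _VALID_RESIDUES else "X" for ch in seq)
        sequences[record.id] = seq
    return sequences


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV of nonnegative integer counts."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric entries in count matrix")
    if np.any(values < 0):
        raise FormatError("negative counts in count matrix")
    if not np.allclose(values, np.round(values)):
        raise FormatError("non-integer counts in count matrix")
    return frame.astype(int)


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_score_table(
    path: str | Path, registry: frozenset[str] = SCORE_REGISTRY
) -> pd.DataFrame:
    """Read a per-protein score TSV with an ``id`` column.

    Score column names must come from ``registry``; duplicate identifiers are
    rejected.
    """
    frame = pd.read_csv(path, sep="\t")
    if "id" not in frame.columns:
        raise FormatError("score table needs an 'id' column")
    unknown = [c for c in frame.columns if c != "id" and c.lower() not in registry]
    if unknown:
        raise FormatError(f"unknown score column(s): {unknown}; registry: {sorted(registry)}")
    frame = frame.rename(columns={c: c.lower() for c in frame.columns if c != "id"})
    frame["id"] = frame["id"].astype(str).str.strip()
    if frame["id"].duplicated().any():
        raise FormatError("duplicate identifiers in score table")
    return frame.set_index("id").astype(float)


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="id")
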