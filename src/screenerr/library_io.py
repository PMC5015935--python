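"""Domain types and tabular I/O shared by every stage of the pipeline.

All tabular files are tab-separated UTF-8 with a single header row; lines
starting with ``#`` are comments (the command-line tools write a provenance
comment as the first line of every output). Barcode sequences can
additionally be exported as FASTA for interoperability with alignment
tooling.

The central containers are:

``VectorDesign``
    The vector layout that matters for recombination: how many base pairs of
    homologous sequence separate the ORF from its barcode, and whether the
    expression promoter is inducible.
``CloneRecord`` / ``Library``
    One barcoded library element, and an ordered collection of elements with
    a relative-abundance vector and optional per-subpool viral titers.
``CountMatrix``
    Elements x samples read counts (raw or normalized to a fixed per-sample
    total), optionally annotated with per-element GC fractions.
``ScenarioConfig``
    The knobs of a simulated screen: MOI, representation, population
    doublings, plasmid-elimination protocol, and the reference-sample mode.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

__all__ = [
    "FormatError",
    "VectorDesign",
    "DEFAULT_DESIGNS",
    "CloneRecord",
    "Library",
    "CountMatrix",
    "ScenarioConfig",
    "REFERENCE_MODES",
    "gc_fraction",
    "read_library",
    "write_library",
    "write_barcode_fasta",
    "read_counts",
    "write_counts",
]

_ACGT = frozenset("ACGT")

#: Reference-sample preparations a simulated screen can be normalized to.
#: ``early_cells``: transduced cells sampled shortly after transduction
#: (plasmid carryover present unless eliminated); ``equilibrated_cells``:
#: cells passaged without induction until carryover has diluted out;
#: ``plasmid_mass_matched``: naked library plasmid used at a mass comparable
#: to the genomic-DNA samples (template copies far in excess);
#: ``linearized_plasmid_in_gdna``: linearized plasmid diluted into carrier
#: genomic DNA so template copies match the transduced-cell samples.
REFERENCE_MODES = (
    "early_cells",
    "equilibrated_cells",
    "plasmid_mass_matched",
    "linearized_plasmid_in_gdna",
)


class FormatError(ValueError):
    """Malformed input file; carries the offending 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def gc_fraction(seq: str) -> float:
    """G+C fraction of a nucleotide string, in [0, 1]."""
    return float(_bio_gc_fraction(seq))


@dataclass(frozen=True)
class VectorDesign:
    """Vector layout parameters that control barcode--ORF recombination risk.

    ``homology_bp`` is the length of homologous sequence separating the ORF
    from its barcode; the longer the interval, the more opportunity the
    reverse transcriptase has to switch templates between the two packaged
    genomes without uncoupling being suppressed.
    """

    name: str
    homology_bp: int
    inducible: bool = False
    promoter_label: str = "CMV"

    def __post_init__(self):
        if self.homology_bp < 0:
            raise ValueError(f"homology_bp must be >= 0, got {self.homology_bp}")


#: The three stock layouts: barcode 5' of the ORF (720 bp of homology
#: between them), barcode immediately 3' of the ORF (96 bp), and the
#: doxycycline-inducible variant of the 3' layout.
DEFAULT_DESIGNS: dict[str, VectorDesign] = {
    "5BC": VectorDesign("5BC", 720, False, "CMV"),
    "3BC": VectorDesign("3BC", 96, False, "CMV"),
    "TRE": VectorDesign("TRE", 96, True, "TRE"),
}


@dataclass(frozen=True)
class CloneRecord:
    """One library element: an ORF (or hairpin) paired with a unique barcode.

    ``gc_fraction`` refers to the amplified template sequence the element
    contributes to the readout PCR (for hairpin libraries, the hairpin
    itself), not necessarily the barcode alone.
    """

    element_id: str
    orf_id: str
    bc_id: str
    bc_seq: str
    gc_fraction: float
    subpool_id: str
    design: VectorDesign

    def __post_init__(self):
        if not self.bc_seq or set(self.bc_seq) - _ACGT:
            raise ValueError(
                f"element {self.element_id!r}: barcode must be a nonempty A/C/G/T string"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(
                f"element {self.element_id!r}: gc_fraction {self.gc_fraction} outside [0, 1]"
            )


@dataclass
class Library:
    """An ordered barcoded library with relative abundances.

    ``abundance`` is a probability vector over clones (renormalized by the
    reader, validated here). ``subpool_titers`` maps subpool id to viral
    titer in CFU/ml when subpools were packaged and titered separately.
    """

    clones: list[CloneRecord]
    abundance: np.ndarray
    subpool_titers: dict[str, float] | None = None

    def __post_init__(self):
        if not self.clones:
            raise ValueError("library must contain at least one clone")
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.clones),):
            raise ValueError("abundance length must match number of clones")
        if np.any(self.abundance < 0):
            raise ValueError("abundance entries must be >= 0")
        if abs(float(self.abundance.sum()) - 1.0) > 1e-9:
            raise ValueError("abundance must sum to 1 within 1e-9")
        ids = [c.element_id for c in self.clones]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate element_id {dup!r}")
        bcs = [c.bc_id for c in self.clones]
        if len(set(bcs)) != len(bcs):
            raise ValueError("bc_id values must be unique within a library")
        if self.subpool_titers is not None:
            missing = {c.subpool_id for c in self.clones} - set(self.subpool_titers)
            if missing:
                raise ValueError(f"subpool(s) without a titer entry: {sorted(missing)}")
        # cached per-element arrays used by the simulators
        self.element_ids = np.array(ids, dtype=object)
        self.orf_ids = np.array([c.orf_id for c in self.clones], dtype=object)
        self.bc_ids = np.array(bcs, dtype=object)
        self.subpool_ids = np.array([c.subpool_id for c in self.clones], dtype=object)
        self.gc = np.array([c.gc_fraction for c in self.clones], dtype=float)
        _, self.orf_codes = np.unique(self.orf_ids, return_inverse=True)

    @property
    def n(self) -> int:
        return len(self.clones)

    def pairing(self) -> set[tuple[str, str]]:
        """The set of (orf_id, bc_id) pairs present in the library."""
        return {(c.orf_id, c.bc_id) for c in self.clones}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": self.element_ids,
                "orf_id": self.orf_ids,
                "bc_id": self.bc_ids,
                "bc_seq": [c.bc_seq for c in self.clones],
                "subpool_id": self.subpool_ids,
                "design": [c.design.name for c in self.clones],
                "abundance": self.abundance,
            }
        )


_LIBRARY_COLUMNS = ("element_id", "orf_id", "bc_id", "bc_seq", "subpool_id", "design")


def _data_line_numbers(path: Path) -> list[int]:
    """1-based file line numbers of non-comment, non-blank lines (header first)."""
    numbers = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip() and not line.lstrip().startswith("#"):
                numbers.append(i)
    return numbers


def read_library(
    path: str | Path,
    designs: dict[str, VectorDesign] | None = None,
) -> Library:
    """Read a library TSV; clone order is file order, abundance renormalized.

    Raises :class:`FormatError` with the offending line number for duplicate
    element ids, non-ACGT barcodes, unknown designs, or negative abundances.
    """
    path = Path(path)
    designs = DEFAULT_DESIGNS if designs is None else designs
    lines = _data_line_numbers(path)
    if not lines:
        raise FormatError(f"{path}: empty library file")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = set(_LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}", line=lines[0])
    if len(lines) != len(df) + 1:  # header + one line per row
        raise FormatError(f"{path}: ragged or malformed rows")

    def lineno(row: int) -> int:
        return lines[row + 1]

    seen: dict[str, int] = {}
    clones: list[CloneRecord] = []
    for row, rec in enumerate(df.itertuples(index=False)):
        eid = str(rec.element_id)
        if eid in seen:
            raise FormatError(
                f"duplicate element_id {eid!r} (first seen line {seen[eid]})",
                line=lineno(row),
            )
        seen[eid] = lineno(row)
        bc_seq = str(rec.bc_seq)
        if set(bc_seq) - _ACGT:
            raise FormatError(f"barcode {bc_seq!r} contains non-ACGT characters", line=lineno(row))
        if rec.design not in designs:
            raise FormatError(f"unknown design {rec.design!r}", line=lineno(row))
        clones.append(
            CloneRecord(
                element_id=eid,
                orf_id=str(rec.orf_id),
                bc_id=str(rec.bc_id),
                bc_seq=bc_seq,
                gc_fraction=gc_fraction(bc_seq),
                subpool_id=str(rec.subpool_id),
                design=designs[rec.design],
            )
        )
    if "abundance" in df.columns:
        try:
            ab = df["abundance"].astype(float).to_numpy()
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric abundance: {exc}") from exc
        neg = np.flatnonzero(ab < 0)
        if neg.size:
            raise FormatError("negative abundance", line=lineno(int(neg[0])))
        total = ab.sum()
        if total <= 0:
            raise FormatError(f"{path}: abundance column sums to zero")
        ab = ab / total
    else:
        ab = np.full(len(clones), 1.0 / len(clones))
    return Library(clones=clones, abundance=ab)


def write_library(library: Library, path: str | Path, comments: list[str] | None = None) -> None:
    """Write a library TSV that :func:`read_library` round-trips exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        library.to_frame().to_csv(fh, sep="\t", index=False)


def write_barcode_fasta(library: Library, path: str | Path) -> None:
    """Export barcode sequences as FASTA, one record per element."""
    records = [
        SeqRecord(Seq(c.bc_seq), id=c.element_id, description=f"orf={c.orf_id} bc={c.bc_id}")
        for c in library.clones
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class CountMatrix:
    """Elements x samples read counts, the backbone of the analysis stage."""

    elements: list[str]
    samples: list[str]
    counts: np.ndarray
    normalized: bool = False
    gc: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float if self.normalized else None)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.elements), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.elements)} elements x {len(self.samples)} samples"
            )
        if len(self.samples) == 0:
            raise ValueError("count matrix must have at least one sample column")
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate element labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if self.gc.shape != (len(self.elements),):
                raise ValueError("gc annotation length must match elements")

    def column(self, sample: str) -> pd.Series:
        j = self.samples.index(sample)
        return pd.Series(self.counts[:, j], index=self.elements, name=sample)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "element_id", self.elements)
        return df

    def with_gc(self, library: Library) -> "CountMatrix":
        """Attach per-element GC fractions from a library (matched on element id)."""
        gc_of = dict(zip(library.element_ids, library.gc))
        missing = [e for e in self.elements if e not in gc_of]
        if missing:
            raise ValueError(f"element(s) absent from library: {missing[:5]}")
        return replace(self, gc=np.array([gc_of[e] for e in self.elements]))


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count TSV (first column element_id, one column per sample)."""
    path = Path(path)
    normalized = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                if "normalized" in line:
                    normalized = True
            elif line.strip():
                break
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no sample columns")
    if df.columns[0] != "element_id":
        raise FormatError(f"{path}: first column must be 'element_id', got {df.columns[0]!r}")
    counts = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise FormatError(f"{path}: non-numeric count values")
    if np.any(np.isnan(counts)):
        raise FormatError(f"{path}: ragged rows (missing count values)")
    if np.any(counts < 0):
        raise FormatError(f"{path}: negative count")
    if not normalized and np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    return CountMatrix(
        elements=[str(e) for e in df["element_id"]],
        samples=[str(s) for s in df.columns[1:]],
        counts=counts,
        normalized=normalized,
    )


def write_counts(cm: CountMatrix, path: str | Path, comments: list[str] | None = None) -> None:
    """Write a count TSV that :func:`read_counts` round-trips losslessly for integers."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        if cm.normalized:
            fh.write("# normalized\n")
        cm.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass
class ScenarioConfig:
    """Parameters of a simulated screen; defaults follow the standard protocol.

    ``moi``: multiplicity of infection (Poisson mean integrations per plated
    cell). ``representation``: surviving transduced cells per library
    element. ``pds``: population doublings between reference and endpoint.
    ``dna_input_fraction``: transfection plasmid mass relative to the
    standard protocol (1.0, 0.2, or 0.1). ``benzonase_units``: nuclease dose
    (U/ml) applied to the viral supernatant; 0 means untreated.
    ``reference_mode``: which reference preparation the screen is normalized
    to (see :data:`REFERENCE_MODES`).

    Readout parameters (nominal PCR cycles, reaction capacity, sequencing
    depth) are included so a config fully determines a dataset.
    """

    moi: float = 0.5
    representation: int = 1000
    pds: float = 10.0
    dna_input_fraction: float = 1.0
    benzonase_units: float = 0.0
    seed: int = 0
    reference_mode: str = "early_cells"
    reference_pd: float = 0.0
    n_cycles: int = 30
    capacity: float = 1e12
    depth_per_element: int = 500
    pseudocount: float = 1.0
    plasmid_excess_factor: float = 200.0
    c0_std: float = 70.0
    decay_per_pd: float = 0.5

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.moi <= 0:
            raise ValueError("moi must be > 0")
        if self.representation < 1:
            raise ValueError("representation must be >= 1")
        if self.pds < 0 or self.reference_pd < 0:
            raise ValueError("population doublings must be >= 0")
        if not 0 < self.dna_input_fraction <= 1:
            raise ValueError("dna_input_fraction must be in (0, 1]")
        if self.benzonase_units < 0:
            raise ValueError("benzonase_units must be >= 0")
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(
                f"reference_mode {self.reference_mode!r} not one of {REFERENCE_MODES}"
            )
        if self.n_cycles < 0 or self.capacity <= 0 or self.depth_per_element < 0:
            raise ValueError("invalid readout parameters")
        if self.c0_std < 0 or self.decay_per_pd < 0 or self.plasmid_excess_factor <= 0:
            raise ValueError("invalid contamination parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        """Load a flat key/value YAML config; unknown keys are rejected."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                fh,
                sort_keys=True,
            )
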