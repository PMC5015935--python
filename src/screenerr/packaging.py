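"""Virion co-packaging, template-switching reverse transcription, transduction.

Retroviral and lentiviral particles each package two RNA genomes. When a
producer cell receives a pooled plasmid library, the two genomes of a
virion are drawn approximately independently from the pool, so a fraction
``1 - sum(p_i**2)`` of virions are heterozygous (their genomes come from
different clones). During reverse transcription the RT enzyme can switch
templates within the homologous interval that separates the ORF from its
barcode; in a heterozygous virion a switch uncouples the pair and the
integrated provirus carries a barcode matched to the wrong ORF. Switches
inside homozygous virions leave no trace, which is why measured chimera
frequencies understate the per-virion switch probability: the detectable
chimera fraction is ``p_switch * (1 - sum(p_i**2))``.

Recombination is modeled as at most one effective switch in the ORF-barcode
interval (a Bernoulli event per provirus); the available data constrain only
the aggregate pair-uncoupling probability, not the per-base crossover path.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library_io import Library, VectorDesign

__all__ = [
    "homozygosity_fraction",
    "RecombinationModel",
    "DEFAULT_SWITCH_RATES",
    "calibrate_switch_rate",
    "default_recombination_model",
    "fit_per_base",
    "switch_probability",
    "Virion",
    "package_virions",
    "reverse_transcribe",
    "ProvirusTable",
    "transduce",
]

#: Per-virion switch probabilities for the stock designs, calibrated so the
#: detectable chimera fraction p*(1 - 1/11) in an equimolar 11-clone pool
#: reproduces the measured assay frequencies (26.15% and 5.45%).
DEFAULT_SWITCH_RATES: dict[str, float] = {"5BC": 0.2877, "3BC": 0.0600, "TRE": 0.0600}


def homozygosity_fraction(abundance, *, atol: float = 1e-8) -> float:
    """Probability both genomes of a virion derive from the same clone.

    Under independent draws from the pool this is ``sum(p_i**2)``; for an
    equimolar pool of ``k`` clones it equals ``1/k`` (9.09% at k = 11).
    """
    p = np.asarray(abundance, dtype=float)
    if np.any(p < 0):
        raise ValueError("abundance entries must be >= 0")
    if abs(float(p.sum()) - 1.0) > atol:
        raise ValueError(f"abundance must sum to 1 (got {p.sum():.6g})")
    return float(np.dot(p, p))


def calibrate_switch_rate(f_detectable: float, h: float) -> float:
    """Per-virion switch probability whose detectable chimera fraction is ``f_detectable``.

    Inverts ``f = p * (1 - h)`` where ``h`` is the homozygous-virion fraction.
    """
    if not 0 <= f_detectable <= 1 or not 0 <= h < 1:
        raise ValueError("f_detectable in [0,1] and h in [0,1) required")
    return f_detectable / (1.0 - h)


@dataclass
class RecombinationModel:
    """Switch probability as a function of vector design.

    ``fixed_per_design`` stores one probability per design name (the
    calibrated default). The per-base modes extrapolate from a rate
    ``lambda`` per bp of homology: linear ``min(1, lambda*L)`` or
    exponential ``1 - exp(-lambda*L)``; both are monotone in homology
    length. Only two calibration points exist, so no functional form is
    asserted as correct.
    """

    mode: str = "fixed_per_design"
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SWITCH_RATES))
    rate_per_bp: float | None = None

    def __post_init__(self):
        if self.mode not in ("fixed_per_design", "per_base_linear", "per_base_exponential"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed_per_design":
            for name, p in self.rates.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"rate for design {name!r} outside [0, 1]")
        elif self.rate_per_bp is None or self.rate_per_bp < 0:
            raise ValueError("per-base modes require rate_per_bp >= 0")


def default_recombination_model() -> RecombinationModel:
    return RecombinationModel()


def fit_per_base(points: list[tuple[int, float]], mode: str = "per_base_linear") -> RecombinationModel:
    """Least-squares fit of a per-base rate to (homology_bp, probability) points.

    For the linear model lambda minimizes ``sum (p - lambda*L)^2`` in closed
    form; the exponential model fits lambda to ``-log(1-p) = lambda*L``.
    """
    if not points:
        raise ValueError("at least one calibration point required")
    L = np.array([bp for bp, _ in points], dtype=float)
    p = np.array([pr for _, pr in points], dtype=float)
    if mode == "per_base_linear":
        lam = float(np.dot(L, p) / np.dot(L, L))
    elif mode == "per_base_exponential":
        y = -np.log1p(-p)
        lam = float(np.dot(L, y) / np.dot(L, L))
    else:
        raise ValueError(f"unknown per-base mode {mode!r}")
    return RecombinationModel(mode=mode, rate_per_bp=lam)


def switch_probability(model: RecombinationModel, design: VectorDesign) -> float:
    """Per-virion probability of one effective template switch for a design."""
    if model.mode == "fixed_per_design":
        if design.name not in model.rates:
            raise KeyError(f"no calibrated rate for design {design.name!r}")
        return float(model.rates[design.name])
    lam = float(model.rate_per_bp)
    if model.mode == "per_base_linear":
        return min(1.0, lam * design.homology_bp)
    return 1.0 - math.exp(-lam * design.homology_bp)


@dataclass(frozen=True)
class Virion:
    """An unordered pair of packaged genomes, as clone indices into a library."""

    genome_a: int
    genome_b: int

    @property
    def homozygous(self) -> bool:
        return self.genome_a == self.genome_b


def package_virions(library: Library, n_virions: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_virions`` genome pairs independently from the library abundance.

    Returns an ``(n_virions, 2)`` integer array of clone indices. Producer
    cells are assumed to receive many plasmids, so genome pairing is free
    mixing with no co-transfection structure.
    """
    if n_virions < 1:
        raise ValueError("n_virions must be >= 1")
    if library.n == 0:
        raise ValueError("empty library")
    return rng.choice(library.n, size=(int(n_virions), 2), p=library.abundance)


def _per_clone_switch_probability(library: Library, model: RecombinationModel | None) -> np.ndarray:
    if model is None:
        return np.zeros(library.n)
    cache: dict[str, float] = {}
    out = np.empty(library.n)
    for i, clone in enumerate(library.clones):
        name = clone.design.name
        if name not in cache:
            cache[name] = switch_probability(model, clone.design)
        out[i] = cache[name]
    return out


def reverse_transcribe(
    virion: Virion | tuple[int, int],
    p_switch: float,
    library: Library,
    rng: np.random.Generator,
) -> tuple[str, str, bool]:
    """Reverse-transcribe one virion; returns (orf_id, bc_id, chimeric).

    With probability ``p_switch`` a single switch occurs between the ORF and
    the barcode, so the ORF derives from one genome and the barcode from the
    other. The chimeric flag is true only when the resulting pair is not a
    pairing present in the library; a homozygous virion can therefore never
    yield a chimera.
    """
    if not 0 <= p_switch <= 1:
        raise ValueError("p_switch must be in [0, 1]")
    a, b = (virion.genome_a, virion.genome_b) if isinstance(virion, Virion) else virion
    switched = bool(rng.random() < p_switch)
    bc_src = b if switched else a
    orf_id = library.orf_ids[a]
    bc_id = library.bc_ids[bc_src]
    chimeric = bool(library.orf_codes[a] != library.orf_codes[bc_src])
    return str(orf_id), str(bc_id), chimeric


@dataclass
class ProvirusTable:
    """Integrated proviruses: per row, the cell, the ORF genome, and the
    genome the barcode was copied from.

    ``orf_source`` / ``bc_source`` are clone indices into ``library``; the
    observed (orf_id, bc_id) pair of a provirus is the ORF of the former
    with the barcode of the latter. ``chimeric`` is true exactly when that
    pair is not a library pairing, which requires a heterozygous source
    virion.
    """

    cell_id: np.ndarray
    orf_source: np.ndarray
    bc_source: np.ndarray
    chimeric: np.ndarray
    library: Library
    n_cells_surviving: int = 0

    @property
    def n(self) -> int:
        return len(self.cell_id)

    def chimera_fraction(self) -> float:
        if self.n == 0:
            raise ValueError("empty provirus table")
        return float(self.chimeric.mean())

    def element_counts(self) -> np.ndarray:
        """Template copies per library element, attributed by barcode (the
        sequenced tag), so chimeric proviruses count toward the barcode's
        element."""
        return np.bincount(self.bc_source, minlength=self.library.n)

    def to_frame(self) -> pd.DataFrame:
        lib = self.library
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "orf_id": lib.orf_ids[self.orf_source],
                "bc_id": lib.bc_ids[self.bc_source],
                "chimeric": self.chimeric,
            }
        )

    def subsample(self, n: int, rng: np.random.Generator) -> "ProvirusTable":
        if n > self.n:
            raise ValueError(f"cannot sample {n} of {self.n} proviruses")
        idx = rng.choice(self.n, size=n, replace=False)
        return ProvirusTable(
            cell_id=self.cell_id[idx],
            orf_source=self.orf_source[idx],
            bc_source=self.bc_source[idx],
            chimeric=self.chimeric[idx],
            library=self.library,
            n_cells_surviving=self.n_cells_surviving,
        )


def transduce(
    library: Library,
    n_cells: int,
    moi: float,
    mode: str = "pooled",
    model: RecombinationModel | None = None,
    rng: np.random.Generator | None = None,
) -> ProvirusTable:
    """Transduce ``n_cells`` at the given MOI and return the provirus table.

    Integrations per plated cell are Poisson(moi); cells with zero
    integrations are dropped, emulating drug selection for integrants.

    ``mode='pooled'``: virions come from pooled packaging, so genome pairs
    are independent draws and template switches in heterozygous virions
    produce chimeras. ``mode='individual_then_pooled'``: each cell is
    transduced with virus packaged from a single clone (the assay's PCR
    control arm), so every virion is homozygous by construction and chimeras
    are impossible at any switch probability.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if moi <= 0:
        raise ValueError("moi must be > 0")
    if mode not in ("pooled", "individual_then_pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng

    integrations = rng.poisson(moi, size=int(n_cells))
    surviving = np.flatnonzero(integrations)
    k = integrations[surviving]
    cell_id = np.repeat(surviving, k)
    m = int(k.sum())
    if m == 0:
        return ProvirusTable(
            cell_id=cell_id,
            orf_source=np.empty(0, dtype=int),
            bc_source=np.empty(0, dtype=int),
            chimeric=np.empty(0, dtype=bool),
            library=library,
            n_cells_surviving=0,
        )

    if mode == "pooled":
        a = rng.choice(library.n, size=m, p=library.abundance)
        b = rng.choice(library.n, size=m, p=library.abundance)
    else:
        # one clone per cell line; all its integrations carry identical genomes
        clone_of_cell = rng.choice(library.n, size=len(surviving), p=library.abundance)
        a = np.repeat(clone_of_cell, k)
        b = a

    p = _per_clone_switch_probability(library, model)[a]
    switched = rng.random(m) < p
    bc_source = np.where(switched, b, a)
    chimeric = library.orf_codes[a] != library.orf_codes[bc_source]
    return ProvirusTable(
        cell_id=cell_id,
        orf_source=a,
        bc_source=bc_source,
        chimeric=chimeric,
        library=library,
        n_cells_surviving=len(surviving),
    )
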