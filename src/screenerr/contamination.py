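"""Packaging-plasmid carryover: load, dilution, and copy-number arithmetic.

Transient transfection leaves residual plasmid in the viral supernatant,
which is carried into the transduced culture and co-purifies with genomic
DNA. Because the plasmid contains the same PCR template as the integrated
provirus, an early reference sample can hold tens of template copies per
cell beyond the ~1 proviral copy, distorting reference abundance
measurements. The excess halves with every population doubling (plasmid is
not replicated) and is lost somewhat faster early on, so it is effectively
gone within ~6 doublings.

Copies per cell at a given time follow

    c(t) = c0 * dna_input_fraction * 10**(-benzonase_log_reduction)
              * 2**(-pds) * exp(-decay_per_pd * pds)

with ``c0`` the standard-protocol initial load (default 70 copies/cell,
anchored to the observed >70-fold plasmid:provirus copy excess) and
``decay_per_pd`` a phenomenological extra loss term covering early plasmid
degradation/uneven uptake.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "DALTONS_PER_BP",
    "PG_PER_DIPLOID_GENOME",
    "ContaminationParams",
    "benzonase_log_reduction",
    "initial_plasmid_load",
    "dilute",
    "plasmid_copy_ratio",
    "SampleState",
    "qpcr_relative_signal",
    "signal_trajectory",
]

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair (g/mol).
DALTONS_PER_BP = 650.0
#: Mass of one diploid human genome (pg).
PG_PER_DIPLOID_GENOME = 6.6

#: Benzonase dose (U/ml) at and above which the full log-reduction applies;
#: doses from 50 U/ml up were equally effective in practice.
_BENZONASE_SATURATING_UNITS = 50.0
_BENZONASE_MAX_LOG_REDUCTION = 3.0


def benzonase_log_reduction(units: float) -> float:
    """log10 reduction of free plasmid for a given Benzonase dose (U/ml).

    Saturates at 3 logs for >= 50 U/ml (sub-0.1-copy residual at the
    standard load), proportional below; the assay reports detection limits
    rather than a rate, so this is a configurable working model.
    """
    if units < 0:
        raise ValueError("units must be >= 0")
    return _BENZONASE_MAX_LOG_REDUCTION * min(1.0, units / _BENZONASE_SATURATING_UNITS)


@dataclass
class ContaminationParams:
    """Protocol-level determinants of the initial plasmid load per cell."""

    c0_std: float = 70.0
    dna_input_fraction: float = 1.0
    benzonase_log_reduction: float = 0.0
    decay_per_pd: float = 0.5

    def __post_init__(self):
        if self.c0_std < 0 or self.benzonase_log_reduction < 0 or self.decay_per_pd < 0:
            raise ValueError("contamination parameters must be >= 0")
        if not 0 < self.dna_input_fraction <= 1:
            raise ValueError("dna_input_fraction must be in (0, 1]")


def initial_plasmid_load(params: ContaminationParams) -> float:
    """Plasmid copies per cell immediately after transduction."""
    return params.c0_std * params.dna_input_fraction * 10.0 ** (-params.benzonase_log_reduction)


def dilute(copies0: float, pds: float, decay_per_pd: float = 0.0) -> float:
    """Plasmid copies per cell after ``pds`` population doublings.

    Pure halving per doubling when ``decay_per_pd`` is 0; the extra
    exponential term models early active loss.
    """
    if pds < 0:
        raise ValueError("pds must be >= 0")
    if copies0 < 0:
        raise ValueError("copies0 must be >= 0")
    return copies0 * 2.0 ** (-pds) * math.exp(-decay_per_pd * pds)


def plasmid_copy_ratio(
    plasmid_pg: float,
    plasmid_len_bp: float,
    gdna_ng: float,
    pg_per_diploid_genome: float = PG_PER_DIPLOID_GENOME,
    integrations_per_genome: float = 1.0,
) -> float:
    """Ratio of plasmid template copies to integrated proviral copies.

    Converts a measured plasmid mass within a genomic-DNA sample into
    molecule counts (at 650 Da per base pair) and compares with the proviral
    copies implied by the genomic mass. 5.8 pg of a 10 kb vector in 50 ng of
    total DNA at one provirus per diploid genome gives a ratio of ~71.
    """
    if plasmid_pg < 0:
        raise ValueError("plasmid_pg must be >= 0")
    if plasmid_len_bp <= 0 or gdna_ng <= 0 or pg_per_diploid_genome <= 0:
        raise ValueError("lengths and masses must be > 0")
    if integrations_per_genome <= 0:
        raise ValueError("integrations_per_genome must be > 0")
    pg_per_molecule = plasmid_len_bp * DALTONS_PER_BP / AVOGADRO * 1e12
    plasmid_copies = plasmid_pg / pg_per_molecule
    proviral_copies = gdna_ng * 1000.0 / pg_per_diploid_genome * integrations_per_genome
    return plasmid_copies / proviral_copies


@dataclass
class SampleState:
    """Per-element template copies in one extracted DNA sample.

    Splits copies into proviral (integrated) and plasmid (carryover) origin;
    ``n_genomes`` is the number of diploid genome equivalents in the sample,
    and ``pd`` the population doublings since transduction.
    """

    proviral: np.ndarray
    plasmid: np.ndarray
    pd: float = 0.0
    n_genomes: float = 0.0
    element_ids: np.ndarray | None = None
    total_dna_ng: float | None = None

    def __post_init__(self):
        self.proviral = np.atleast_1d(np.asarray(self.proviral, dtype=float))
        self.plasmid = np.atleast_1d(np.asarray(self.plasmid, dtype=float))
        if self.proviral.shape != self.plasmid.shape:
            raise ValueError("proviral and plasmid copies must align")
        if np.any(self.proviral < 0) or np.any(self.plasmid < 0):
            raise ValueError("copies must be >= 0")
        if self.pd < 0:
            raise ValueError("pd must be >= 0")
        if self.n_genomes <= 0:
            self.n_genomes = float(self.proviral.sum()) or 1.0

    def templates(self) -> np.ndarray:
        return self.proviral + self.plasmid

    def to_frame(self) -> pd.DataFrame:
        ids = (
            self.element_ids
            if self.element_ids is not None
            else np.array([f"e{i}" for i in range(len(self.proviral))], dtype=object)
        )
        return pd.DataFrame(
            {"element_id": ids, "proviral_copies": self.proviral, "plasmid_copies": self.plasmid}
        )


def qpcr_relative_signal(
    state: SampleState,
    elements=None,
    control_copies_per_genome: float = 2.0,
) -> float:
    """Combined plasmid + proviral template signal, relative to one provirus per genome.

    Models relative quantitation against a genomic single-locus control (two
    copies per diploid genome); the control's copy number cancels out of the
    relative quantity, so the baseline -- one integrated provirus per genome
    and no plasmid -- is defined as 1. The signal is additive in proviral
    and plasmid copies: equal plasmid and proviral copies read out as 2x
    baseline.
    """
    if control_copies_per_genome <= 0:
        raise ValueError("control_copies_per_genome must be > 0")
    if elements is None:
        sel: object = slice(None)
    elif state.element_ids is not None and all(isinstance(e, str) for e in elements):
        sel = np.isin(state.element_ids, list(elements))
    else:
        sel = np.asarray(list(elements))
    copies = float(state.proviral[sel].sum() + state.plasmid[sel].sum())
    return copies / state.n_genomes


def signal_trajectory(
    params: ContaminationParams,
    pds,
    integrations_per_genome: float = 1.0,
) -> pd.DataFrame:
    """Relative combined signal versus population doublings (qPCR-style curve).

    At each timepoint the proviral contribution is constant
    (``integrations_per_genome``) and the plasmid contribution is the diluted
    initial load, so the curve starts at ``1 + c0/ipg`` and decays to 1.
    """
    pds = np.asarray(list(pds), dtype=float)
    c0 = initial_plasmid_load(params)
    plasmid = np.array([dilute(c0, t, params.decay_per_pd) for t in pds])
    relative = (integrations_per_genome + plasmid) / integrations_per_genome
    return pd.DataFrame({"pd": pds, "plasmid_copies_per_cell": plasmid, "relative_signal": relative})
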