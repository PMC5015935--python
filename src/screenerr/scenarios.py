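"""End-to-end synthetic screen scenarios.

Wires the packaging, contamination, and PCR models into reproducible
datasets with the statistical structure of the real experiments:

* an 11-clone ORF-barcode sublibrary packaged pooled or individually (the
  recombination assay);
* multi-subpool libraries with unequal titers (carryover scales with the
  supernatant volume added, i.e. inversely with titer);
* a 1000-element nontargeting hairpin library in five exact GC strata
  (40/45/50/55/60%), the mock screen used to isolate PCR GC bias;
* fitness effects (enriching / depleting / neutral with drift) over 10
  population doublings at fixed representation.

A scenario run is: transduce -> build the reference sample (proviral plus
contaminating plasmid templates, per the configured reference mode) ->
grow -> endpoint sample -> amplify both samples under one PCR
parameterization -> multinomial sequencing -> a pair of count matrices plus
the ground-truth log2 fold changes (defined on expected abundances in the
infinite-population limit, so stochastic runs can be scored against them).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .library_io import (
    CloneRecord,
    CountMatrix,
    DEFAULT_DESIGNS,
    Library,
    ScenarioConfig,
    VectorDesign,
    gc_fraction,
    write_counts,
    write_library,
)
from .packaging import (
    ProvirusTable,
    RecombinationModel,
    default_recombination_model,
    transduce,
)
from .contamination import ContaminationParams, benzonase_log_reduction, dilute, initial_plasmid_load
from .pcr import EfficiencyParams, amplify, sequence_sample
from .analysis import GcBiasReport, RecombEstimate, gc_bias_test, log2fc, normalize_counts, recombination_estimate

__all__ = [
    "FitnessSpec",
    "make_orf_bc_library",
    "make_mock_shrna_library",
    "MOCK_GC_STRATA",
    "simulate_growth",
    "ScreenDataset",
    "run_screen_scenario",
    "run_recomb_assay_scenario",
]

_BASES = np.array(list("ACGT"))

#: Exact GC strata of the mock nontargeting-hairpin library.
MOCK_GC_STRATA = (0.40, 0.45, 0.50, 0.55, 0.60)


@dataclass
class FitnessSpec:
    """Per-ORF selection coefficients, in doublings.

    An ORF with coefficient ``s`` grows ``2**(1+s)``-fold per population
    doubling of the bulk culture (neutral: ``2``), so its expected relative
    weight changes by ``2**(pds * s)`` over a screen. Presets follow the
    canonical proliferation regulators: an enricher like CCND1 (s > 0) and
    a depleter like CDKN1A (s < 0); everything else is neutral and subject
    only to drift.
    """

    s_by_orf: dict[str, float] = field(default_factory=dict)
    default_s: float = 0.0

    ENRICHER_S = 0.1
    DEPLETER_S = -0.1

    def __post_init__(self):
        for orf, s in self.s_by_orf.items():
            if 1.0 + s <= 0:
                raise ValueError(f"orf {orf!r}: 1 + s must be > 0")
        if 1.0 + self.default_s <= 0:
            raise ValueError("1 + default_s must be > 0")

    @classmethod
    def neutral(cls) -> "FitnessSpec":
        return cls()

    @classmethod
    def with_effects(
        cls,
        enrichers=(),
        depleters=(),
        s_enrich: float | None = None,
        s_deplete: float | None = None,
    ) -> "FitnessSpec":
        s_enrich = cls.ENRICHER_S if s_enrich is None else s_enrich
        s_deplete = cls.DEPLETER_S if s_deplete is None else s_deplete
        table = {orf: s_enrich for orf in enrichers}
        table.update({orf: s_deplete for orf in depleters})
        return cls(s_by_orf=table)

    def s_per_element(self, library: Library) -> np.ndarray:
        return np.array([self.s_by_orf.get(orf, self.default_s) for orf in library.orf_ids])


def _unique_random_seqs(
    n: int, length: int, rng: np.random.Generator, gc_count: int | None = None
) -> list[str]:
    """Collision-free random sequences; optionally with an exact G+C count."""
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        if gc_count is None:
            seq = "".join(rng.choice(_BASES, size=length))
        else:
            letters = np.concatenate(
                [
                    rng.choice(["G", "C"], size=gc_count),
                    rng.choice(["A", "T"], size=length - gc_count),
                ]
            )
            seq = "".join(rng.permutation(letters))
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


def make_orf_bc_library(
    n_orfs: int,
    bcs_per_orf: int = 1,
    bc_len: int = 30,
    design: VectorDesign | str = "3BC",
    subpools: int = 1,
    rng: np.random.Generator | None = None,
    subpool_titers: dict[str, float] | None = None,
) -> Library:
    """Build an ORF library with ``bcs_per_orf`` unique 30-bp barcodes per ORF.

    Barcodes are uniform random over ACGT and collision-free; elements are
    assigned to subpools round-robin with uniform abundance.
    """
    if n_orfs < 1 or bcs_per_orf < 1 or bc_len < 1 or subpools < 1:
        raise ValueError("n_orfs, bcs_per_orf, bc_len, subpools must be >= 1")
    n = n_orfs * bcs_per_orf
    if n > 4**bc_len:
        raise ValueError(f"{n} barcodes exceed the 4^{bc_len} sequence space")
    if isinstance(design, str):
        design = DEFAULT_DESIGNS[design]
    rng = np.random.default_rng() if rng is None else rng
    seqs = _unique_random_seqs(n, bc_len, rng)
    clones = []
    for i in range(n_orfs):
        for j in range(bcs_per_orf):
            k = i * bcs_per_orf + j
            clones.append(
                CloneRecord(
                    element_id=f"ORF{i:04d}_BC{k:05d}",
                    orf_id=f"ORF{i:04d}",
                    bc_id=f"BC{k:05d}",
                    bc_seq=seqs[k],
                    gc_fraction=gc_fraction(seqs[k]),
                    subpool_id=f"pool{k % subpools:02d}",
                    design=design,
                )
            )
    return Library(
        clones=clones,
        abundance=np.full(n, 1.0 / n),
        subpool_titers=subpool_titers,
    )


def make_mock_shrna_library(
    rng: np.random.Generator | None = None,
    shrnas_per_stratum: int = 200,
    hairpin_len: int = 60,
) -> Library:
    """The mock nontargeting-hairpin library: five pools of uniform GC content.

    Each of the five strata (40/45/50/55/60% GC) contains
    ``shrnas_per_stratum`` hairpins whose template sequences have *exactly*
    the stratum's GC fraction; one subpool per stratum. 1000 elements at
    the defaults.
    """
    rng = np.random.default_rng() if rng is None else rng
    clones = []
    k = 0
    for g in MOCK_GC_STRATA:
        gc_count = round(g * hairpin_len)
        if not math.isclose(gc_count / hairpin_len, g, abs_tol=1e-12):
            raise ValueError(f"hairpin_len {hairpin_len} cannot realize GC {g} exactly")
        for seq in _unique_random_seqs(shrnas_per_stratum, hairpin_len, rng, gc_count=gc_count):
            clones.append(
                CloneRecord(
                    element_id=f"sh{k:04d}",
                    orf_id=f"sh{k:04d}",  # nontargeting: each hairpin is its own element
                    bc_id=f"hp{k:04d}",
                    bc_seq=seq,
                    gc_fraction=g,
                    subpool_id=f"gc{round(100 * g)}",
                    design=DEFAULT_DESIGNS["TRE"],
                )
            )
            k += 1
    n = len(clones)
    return Library(clones=clones, abundance=np.full(n, 1.0 / n))


def _grow(a, s, pds, size, rng, stochastic):
    """Selection + multinomial-drift recurrence on an abundance vector."""
    a = a / a.sum()
    if not stochastic or rng is None:
        w = a * 2.0 ** (pds * s)
        return w / w.sum()
    steps = int(math.floor(pds))
    for _ in range(steps):
        w = a * 2.0**s
        w = w / w.sum()
        a = rng.multinomial(size, w) / size
    frac = pds - steps
    if frac > 0:
        w = a * 2.0 ** (frac * s)
        a = w / w.sum()
    return a


def simulate_growth(
    abundance,
    s,
    pds: float,
    representation: int,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> np.ndarray:
    """Grow a population for ``pds`` doublings under per-element selection.

    Expected endpoint weights are ``a_i * 2**(pds * s_i)`` renormalized (the
    common ``2**pds`` bulk growth factors out). In stochastic mode, each
    whole doubling applies the selection weights and then multinomially
    resamples ``representation * n`` cells, so drift variance shrinks as
    1/representation; any fractional doubling is applied deterministically.
    """
    a = np.asarray(abundance, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), a.shape)
    if pds < 0:
        raise ValueError("pds must be >= 0")
    if representation < 1:
        raise ValueError("representation must be >= 1")
    if np.any(a < 0) or a.sum() <= 0:
        raise ValueError("abundance must be nonnegative with positive sum")
    return _grow(a, s, pds, int(representation) * len(a), rng, stochastic)


@dataclass
class ScreenDataset:
    """A complete synthetic screen: inputs, intermediate state, and readouts."""

    library: Library
    provirus: ProvirusTable
    counts_ref: CountMatrix
    counts_end: CountMatrix
    truth_log2fc: np.ndarray
    config: ScenarioConfig
    n_eff_ref: float = float("nan")
    n_eff_end: float = float("nan")

    def log2fc(self, pseudocount: float | None = None, total: float = 1e6) -> pd.Series:
        """Normalized log2 fold change, endpoint over reference."""
        pc = self.config.pseudocount if pseudocount is None else pseudocount
        ref = normalize_counts(self.counts_ref, total).column("reference")
        end = normalize_counts(self.counts_end, total).column("endpoint")
        return log2fc(ref, end, pc)

    def gc_bias(self, **kwargs) -> GcBiasReport:
        return gc_bias_test(self.log2fc(**kwargs).to_numpy(), self.library.gc)

    def write(self, outdir: str | Path, include_provirus: bool = True, comments=None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        comments = list(comments or [])
        write_library(self.library, outdir / "library.tsv", comments)
        write_counts(self.counts_ref, outdir / "counts_ref.tsv", comments)
        write_counts(self.counts_end, outdir / "counts_end.tsv", comments)
        truth = pd.DataFrame(
            {"element_id": self.library.element_ids, "truth_log2fc": self.truth_log2fc}
        )
        with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            truth.to_csv(fh, sep="\t", index=False)
        if include_provirus:
            with open(outdir / "provirus.tsv", "w", encoding="utf-8") as fh:
                for c in comments:
                    fh.write(f"# {c}\n")
                self.provirus.to_frame().to_csv(fh, sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def _plasmid_weights(library: Library, titer_weighted: bool) -> np.ndarray:
    """Per-element composition of carryover plasmid.

    Subpools are added at equal cell representation, so the supernatant
    volume -- and with it the plasmid -- contributed by a subpool scales
    inversely with its titer.
    """
    w = library.abundance.copy()
    if titer_weighted and library.subpool_titers:
        inv = np.array([1.0 / library.subpool_titers[s] for s in library.subpool_ids])
        w = w * inv
    return w / w.sum()


def run_screen_scenario(
    config: ScenarioConfig,
    library: Library,
    fitness: FitnessSpec | None = None,
    model: RecombinationModel | None = None,
    pcr_params: EfficiencyParams | None = None,
) -> ScreenDataset:
    """Simulate one screen under a scenario configuration.

    The reference sample is assembled according to ``config.reference_mode``:

    ``early_cells``
        Transduced cells at ``reference_pd`` doublings; templates are
        proviral copies plus the (possibly Benzonase-reduced / input-
        reduced) plasmid carryover, apportioned across elements by library
        abundance and inversely to subpool titer.
    ``equilibrated_cells``
        The uninduced arm: the same population passaged for ``pds``
        doublings (neutral drift) before sampling, by which time carryover
        has diluted out and template totals match the endpoint.
    ``plasmid_mass_matched``
        Naked library plasmid at a mass comparable to the gDNA samples,
        i.e. ``plasmid_excess_factor``-fold more template copies than the
        cellular samples.
    ``linearized_plasmid_in_gdna``
        Linearized plasmid diluted into carrier gDNA so template copies
        match the transduced-cell sample.

    Both samples are amplified under one PCR parameterization to a fixed
    nominal cycle count with a fixed per-reaction capacity, so differences
    in template input surface as differences in effective cycles.
    """
    config.validate()
    fitness = FitnessSpec.neutral() if fitness is None else fitness
    pcr_params = EfficiencyParams() if pcr_params is None else pcr_params
    rng_t = substream(config.seed, "transduce")
    rng_ref = substream(config.seed, "reference")
    rng_growth = substream(config.seed, "growth")
    rng_seq = substream(config.seed, "sequencing")

    n_elem = library.n
    survival = 1.0 - math.exp(-config.moi)
    n_cells = max(1, round(config.representation * n_elem / survival))
    provirus = transduce(library, n_cells, config.moi, "pooled", model, rng_t)
    prov_counts = provirus.element_counts().astype(float)
    m_templates = prov_counts.sum()
    if m_templates == 0:
        raise ValueError("no integrations; increase n_cells or moi")
    n_genomes = provirus.n_cells_surviving

    cparams = ContaminationParams(
        c0_std=config.c0_std,
        dna_input_fraction=config.dna_input_fraction,
        benzonase_log_reduction=benzonase_log_reduction(config.benzonase_units),
        decay_per_pd=config.decay_per_pd,
    )
    c0 = initial_plasmid_load(cparams)
    carryover_w = _plasmid_weights(library, titer_weighted=True)
    plasmid_pool_w = _plasmid_weights(library, titer_weighted=False)

    s = fitness.s_per_element(library)
    # A chimeric provirus grows with the fitness of the ORF it is physically
    # linked to, while its reads report the barcode's element. Growth is
    # therefore tracked on the sparse joint (barcode element, ORF source)
    # table, and collapsed to barcode elements only at readout.
    pair_idx = provirus.bc_source.astype(np.int64) * n_elem + provirus.orf_source
    pair_uniq, pair_counts = np.unique(pair_idx, return_counts=True)
    pair_bc = (pair_uniq // n_elem).astype(np.intp)
    pair_s = s[pair_uniq % n_elem]
    pop_size = int(config.representation) * n_elem

    mode = config.reference_mode
    if mode == "early_cells":
        plasmid_ref = dilute(c0, config.reference_pd, cparams.decay_per_pd) * n_genomes
        ref_templates = prov_counts + plasmid_ref * carryover_w
    elif mode == "equilibrated_cells":
        drift_ab = _grow(
            pair_counts.astype(float), np.zeros(len(pair_counts)), config.pds, pop_size, rng_ref, True
        )
        plasmid_ref = dilute(c0, config.pds, cparams.decay_per_pd) * n_genomes
        ref_templates = (
            np.bincount(pair_bc, weights=drift_ab, minlength=n_elem) * m_templates
            + plasmid_ref * carryover_w
        )
    elif mode == "plasmid_mass_matched":
        ref_templates = config.plasmid_excess_factor * m_templates * plasmid_pool_w
    else:  # linearized_plasmid_in_gdna
        ref_templates = m_templates * plasmid_pool_w

    end_pair_ab = _grow(pair_counts.astype(float), pair_s, config.pds, pop_size, rng_growth, True)
    end_ab = np.bincount(pair_bc, weights=end_pair_ab, minlength=n_elem)
    plasmid_end = dilute(c0, config.reference_pd + config.pds, cparams.decay_per_pd) * n_genomes
    end_templates = end_ab * m_templates + plasmid_end * carryover_w

    ref_run = amplify(ref_templates, library.gc, config.n_cycles, config.capacity, pcr_params)
    end_run = amplify(end_templates, library.gc, config.n_cycles, config.capacity, pcr_params)
    depth = config.depth_per_element * n_elem
    reads_ref = sequence_sample(ref_run.realized, depth, rng_seq)
    reads_end = sequence_sample(end_run.realized, depth, rng_seq)

    elements = [str(e) for e in library.element_ids]
    counts_ref = CountMatrix(elements, ["reference"], reads_ref[:, None], gc=library.gc)
    counts_end = CountMatrix(elements, ["endpoint"], reads_end[:, None], gc=library.gc)
    expected_end = library.abundance * 2.0 ** (config.pds * s)
    truth = config.pds * s - math.log2(expected_end.sum() / library.abundance.sum())
    return ScreenDataset(
        library=library,
        provirus=provirus,
        counts_ref=counts_ref,
        counts_end=counts_end,
        truth_log2fc=truth,
        config=config,
        n_eff_ref=ref_run.n_eff,
        n_eff_end=end_run.n_eff,
    )


def run_recomb_assay_scenario(
    n_clones: int = 11,
    design: VectorDesign | str = "5BC",
    mode: str = "pooled",
    n_sequenced: int = 65,
    model: RecombinationModel | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    moi: float = 0.5,
) -> tuple[ProvirusTable, RecombEstimate]:
    """Simulate the recombination assay and estimate frequencies from it.

    Packages an equimolar ``n_clones`` sublibrary either pooled (switches in
    heterozygous virions produce detectable chimeras) or individually then
    pooled (the PCR-control arm: every virion homozygous, zero chimeras at
    any switch probability), samples ``n_sequenced`` proviruses, and feeds
    the observed (orf, bc) pairs to the estimator with the homozygosity
    correction.
    """
    if n_sequenced < 1:
        raise ValueError("n_sequenced must be >= 1")
    if mode in ("individual", "individual_then_pooled"):
        transduce_mode = "individual_then_pooled"
    elif mode == "pooled":
        transduce_mode = "pooled"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = substream(seed, "recomb_assay")
    model = default_recombination_model() if model is None else model
    lib_rng = np.random.default_rng(rng.integers(2**31))
    library = make_orf_bc_library(n_clones, 1, 30, design, rng=lib_rng)
    # plate enough cells that the expected integration count safely exceeds
    # the number of proviruses to be sequenced
    n_cells = int(math.ceil(4 * n_sequenced / moi)) + 64
    provirus = transduce(library, n_cells, moi, transduce_mode, model, rng)
    sample = provirus.subsample(n_sequenced, rng)
    est = recombination_estimate(sample, library)
    return sample, est
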