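"""Stochastic end-to-end screen simulator and synthetic-data generators.

This module provides the statistical stand-in for the experimental stages
of a droplet-based single-cell BiTE screen:

* a spiked cell population (rare functional clones in a negative
  background),
* Poisson co-encapsulation of library cells and two orthogonal reporter
  channels into monodisperse droplets,
* per-reporter Bernoulli activation (functional-induced plus a basal
  false-positive level) with Gaussian endpoint signal intensities,
* μ+kσ gating, per-channel detection and single-cell PCR recovery,
* a recovery titration producing the observations the recovery-rate
  regression consumes, and
* a synthetic long-read generator (substitution errors, random strand)
  with ground-truth labels for validating the amplicon classifier.

It also builds the synthetic reference panel used throughout the test
suite: the real variable-domain sequences of the published binders are not
public, so seeded synthetic stand-in domains carry the same panel
structure (names, targets, linkers, orientations, CDRH3 windows).

Every operation is reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import math

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .amplicon_classify import CCSRead
from .droplet_stats import EncapsulationConfig, GateConfig, gate_threshold
from .library_design import (
    AMINO_ACIDS,
    ALL_ORIENTATIONS,
    AnchorSet,
    BiTEVariant,
    DegenerateScheme,
    LibraryDefinition,
    LinkerRef,
    ScFvRef,
    Target,
)

__all__ = [
    "Spike",
    "ActivationModel",
    "ReadErrorModel",
    "SimConfig",
    "Droplets",
    "ActivationResult",
    "SimulatedScreen",
    "synthetic_panel",
    "build_population",
    "default_droplet_count",
    "simulate_encapsulation",
    "simulate_activation",
    "simulate_sort_and_recover",
    "run_screen",
    "run_titration",
    "simulate_ccs_reads",
    "analytic_recovery_probability",
]

BACKGROUND = "background"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spike:
    """A clone spiked into the background population."""

    variant_id: str
    abundance: float  # fraction of the population, e.g. 8e-5 for 0.008%
    functional: bool = True

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@dataclass(frozen=True)
class ActivationModel:
    """Endpoint reporter-activation model.

    A reporter co-encapsulated with ≥1 functional library cell activates
    with probability ``p_activate_given_functional`` (defaults to the 40%
    droplet activation efficiency measured for the benchmark BiTE); any
    reporter can also activate spuriously at ``basal_fpr`` (default 1%,
    the single-reporter false-positive tolerance). Signal intensities are
    Gaussian per state; activated reporters draw from the activated
    distribution regardless of why they activated.
    """

    p_activate_given_functional: float = 0.40
    basal_fpr: float = 0.01
    mu_negative: float = 100.0
    sigma_negative: float = 10.0
    mu_activated: float = 1000.0
    sigma_activated: float = 50.0

    def __post_init__(self) -> None:
        for name in ("p_activate_given_functional", "basal_fpr"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma_negative < 0 or self.sigma_activated < 0:
            raise ValueError("signal sigmas must be >= 0")


@dataclass(frozen=True)
class ReadErrorModel:
    """Residual substitution-error model for synthetic consensus reads."""

    substitution_rate: float = 0.002
    depth: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _default_gates() -> Tuple[GateConfig, ...]:
    return (GateConfig(100.0, 10.0, 4.0), GateConfig(100.0, 10.0, 4.0))


@dataclass
class SimConfig:
    """Full configuration of one simulated screen.

    Defaults are the screen's operating point: λ=0.3 library cells and λ=3
    reporters per 77 µm droplet split over two orthogonal channels, 40%
    activation with 1% basal false positives, 90% per-channel detection,
    77.5% single-cell PCR success, and μ+4σ gates per channel.
    """

    seed: int = 0
    population_size: int = 1_000_000
    spikes: Sequence[Spike] = ()
    encapsulation: EncapsulationConfig = field(default_factory=EncapsulationConfig)
    activation: ActivationModel = field(default_factory=ActivationModel)
    detection_efficiency: float = 0.90
    pcr_success: float = 0.775
    gates: Sequence[GateConfig] = field(default_factory=_default_gates)
    n_droplets: Optional[int] = None
    spike_mode: str = "exact"  # "exact" | "sampled"

    def __post_init__(self) -> None:
        if sum(s.abundance for s in self.spikes) > 1:
            raise ValueError("summed spike abundances exceed 1")
        for name in ("detection_efficiency", "pcr_success"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spike_mode not in ("exact", "sampled"):
            raise ValueError(f"spike_mode {self.spike_mode!r}")

    @property
    def n_channels(self) -> int:
        return len(self.gates)


# ---------------------------------------------------------------------------
# Synthetic reference panel
# ---------------------------------------------------------------------------

_VH_LEN = 122
_VL_LEN = 108
_CDRH3 = (95, 107)  # 12-residue window in every CD19 VH

_CD19_NAMES = ("4G7", "B43", "FMC63", "JUNO241")
_CD3_NAMES = ("L2K", "OKT3", "TRX4", "h38E4.v1")

_FORBIDDEN_MOTIFS = ("GGGGS", "EAAAK", "HHH")


def _random_domain(rng: np.random.Generator, length: int) -> str:
    """Random amino-acid domain free of linker/His motifs."""
    aas = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    while True:
        seq = rng.choice(aas, size=length).tobytes().decode("ascii")
        if not any(m in seq for m in _FORBIDDEN_MOTIFS):
            return seq


def default_linker_panel() -> Tuple[LinkerRef, ...]:
    """The four-member inter-scFv linker panel (flexible/rigid × short/long)."""
    return (
        LinkerRef("flex_short", "GGGGS", "flexible", "short"),
        LinkerRef("flex_long", "GGGGS" * 3, "flexible", "long"),
        LinkerRef("rigid_short", "AEAAAKA", "rigid", "short"),
        LinkerRef("rigid_long", "AEAAAKEAAAKA", "rigid", "long"),
    )


def synthetic_panel(seed: int = 0) -> LibraryDefinition:
    """Build a synthetic library definition mirroring the published design.

    The panel structure is real — four CD19 binders (4G7, B43, FMC63,
    JUNO241) with a 12-residue CDRH3 scanning window, four CD3 binders
    (L2K, OKT3, TRX4, h38E4.v1), the four-member linker panel and all four
    VL/VH orientation pairs under an NNW scanning scheme — but the
    variable-domain amino-acid sequences are seeded synthetic stand-ins
    (the real sequences are proprietary), screened so that no linker or
    His-tag motif can occur inside a domain.
    """
    rng = np.random.default_rng(seed)
    cd19 = tuple(
        ScFvRef(
            name,
            Target.CD19,
            _random_domain(rng, _VH_LEN),
            _random_domain(rng, _VL_LEN),
            cdrh3_start=_CDRH3[0],
            cdrh3_end=_CDRH3[1],
        )
        for name in _CD19_NAMES
    )
    cd3 = tuple(
        ScFvRef(name, Target.CD3, _random_domain(rng, _VH_LEN), _random_domain(rng, _VL_LEN))
        for name in _CD3_NAMES
    )
    return LibraryDefinition(
        cd19_refs=cd19,
        cd3_refs=cd3,
        linkers=default_linker_panel(),
        orientations=ALL_ORIENTATIONS,
        scheme=DegenerateScheme(),
        anchors=AnchorSet(),
    )


# ---------------------------------------------------------------------------
# Population and encapsulation
# ---------------------------------------------------------------------------

def build_population(
    spikes: Sequence[Spike],
    size: int,
    rng: np.random.Generator,
    mode: str = "exact",
) -> Tuple[np.ndarray, List[str], Dict[str, int]]:
    """Construct the genotype array of a spiked cell population.

    Returns (genotype codes, label list, realized spike counts). Code 0 is
    the non-functional background. ``mode="exact"`` places
    round(abundance × size) copies of each spike; ``mode="sampled"`` draws
    binomial counts. The array is shuffled so genotype order carries no
    information.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError(f"mode {mode!r}")
    labels = [BACKGROUND] + [s.variant_id for s in spikes]
    counts: Dict[str, int] = {}
    codes = np.zeros(size, dtype=np.int32)
    cursor = 0
    for idx, spike in enumerate(spikes, start=1):
        if mode == "exact":
            n = int(round(spike.abundance * size))
        else:
            n = int(rng.binomial(size, spike.abundance))
        n = min(n, size - cursor)
        codes[cursor : cursor + n] = idx
        counts[spike.variant_id] = n
        cursor += n
    rng.shuffle(codes)
    return codes, labels, counts


def default_droplet_count(population_size: int, lambda_library: float) -> int:
    """Droplet count keeping expected library-cell usage ≤ 90% of the pool."""
    return max(1, int(0.9 * population_size / lambda_library))


@dataclass
class Droplets:
    """Per-droplet occupancy of one encapsulation run."""

    lib_counts: np.ndarray  # (n,)
    genotype_offsets: np.ndarray  # (n+1,) into `genotypes`
    genotypes: np.ndarray  # drawn genotype codes, concatenated
    reporter_counts: np.ndarray  # (n, n_channels)

    @property
    def n_droplets(self) -> int:
        return len(self.lib_counts)

    def droplet_genotypes(self, i: int) -> np.ndarray:
        return self.genotypes[self.genotype_offsets[i] : self.genotype_offsets[i + 1]]


def simulate_encapsulation(
    population: np.ndarray,
    config: EncapsulationConfig,
    n_droplets: int,
    rng: np.random.Generator,
    n_channels: int = 2,
) -> Droplets:
    """Poisson co-encapsulation of library cells and reporters.

    Library-cell and per-channel reporter counts are independent Poisson
    (the reporter λ is split equally across channels, matching a 1:1
    reporter mix). Library genotypes are drawn without replacement from
    the population; if the Poisson draw asks for more cells than remain,
    trailing droplets receive the leftover cells (the pool runs dry).
    """
    lam_lib = config.lambda_library
    lam_chan = config.lambda_reporter / n_channels
    lib_counts = rng.poisson(lam_lib, n_droplets).astype(np.int64)
    total = int(lib_counts.sum())
    pool = rng.permutation(population)
    if total > len(pool):
        # truncate trailing droplets once the pool is exhausted
        cum = np.cumsum(lib_counts)
        over = cum > len(pool)
        first = int(np.argmax(over))
        lib_counts[first] -= int(cum[first] - len(pool))
        lib_counts[first + 1 :] = 0
        total = len(pool)
    offsets = np.zeros(n_droplets + 1, dtype=np.int64)
    np.cumsum(lib_counts, out=offsets[1:])
    genotypes = pool[:total]
    reporter_counts = rng.poisson(lam_chan, size=(n_droplets, n_channels)).astype(np.int64)
    return Droplets(lib_counts, offsets, genotypes, reporter_counts)


# ---------------------------------------------------------------------------
# Activation, gating, sorting, recovery
# ---------------------------------------------------------------------------

@dataclass
class ActivationResult:
    functional_droplet: np.ndarray  # (n,) bool
    activated_counts: np.ndarray  # (n, n_channels)
    signals: np.ndarray  # (n, n_channels); -inf for reporter-free channels


def _max_of_normals(
    rng: np.random.Generator, k: np.ndarray, mu: float, sigma: float
) -> np.ndarray:
    """Sample max of k iid Normal(mu, sigma) per entry via inverse-CDF.

    Entries with k == 0 return -inf. Uses M = mu + sigma·Φ⁻¹(U^(1/k)).
    """
    from scipy.stats import norm

    out = np.full(k.shape, -np.inf, dtype=float)
    pos = k > 0
    if pos.any():
        u = rng.random(int(pos.sum()))
        out[pos] = mu + sigma * norm.ppf(u ** (1.0 / k[pos]))
    return out


def simulate_activation(
    droplets: Droplets,
    model: ActivationModel,
    rng: np.random.Generator,
    functional_codes: Sequence[int],
) -> ActivationResult:
    """Per-reporter Bernoulli activation with Gaussian endpoint signals.

    In droplets holding ≥1 functional library cell each reporter activates
    with probability 1-(1-p_activate)(1-basal); elsewhere at the basal
    rate. The per-channel signal is the brightest reporter in the channel.
    """
    n, n_channels = droplets.reporter_counts.shape
    functional_codes = np.asarray(sorted(set(functional_codes)), dtype=droplets.genotypes.dtype)
    cell_functional = np.isin(droplets.genotypes, functional_codes)
    functional = np.zeros(n, dtype=bool)
    if cell_functional.any():
        functional = np.add.reduceat(
            np.append(cell_functional, False), droplets.genotype_offsets[:-1]
        ).astype(bool)
        functional &= droplets.lib_counts > 0
    q_func = 1.0 - (1.0 - model.p_activate_given_functional) * (1.0 - model.basal_fpr)
    p_act = np.where(functional, q_func, model.basal_fpr)[:, None]
    activated = rng.binomial(droplets.reporter_counts, p_act)
    quiet = droplets.reporter_counts - activated
    signals = np.maximum(
        _max_of_normals(rng, activated, model.mu_activated, model.sigma_activated),
        _max_of_normals(rng, quiet, model.mu_negative, model.sigma_negative),
    )
    return ActivationResult(functional, activated, signals)


@dataclass
class SimulatedScreen:
    """Outcome of one simulated screen with per-spike accounting."""

    droplets: Droplets
    activation: ActivationResult
    sorted_mask: np.ndarray
    recovered_counts: Dict[str, int]
    observations: pd.DataFrame  # per-spike RecoveryObservation rows
    losses: pd.DataFrame  # itemized per-spike copy accounting


def simulate_sort_and_recover(
    droplets: Droplets,
    activation: ActivationResult,
    gates: Sequence[GateConfig],
    detection_efficiency: float,
    pcr_success: float,
    rng: np.random.Generator,
    labels: Sequence[str],
    spiked_counts: Dict[str, int],
    run_id: str = "run0",
) -> SimulatedScreen:
    """Gate, detect, sort and PCR-recover genotypes from positive droplets.

    A droplet is sorted iff every channel's signal exceeds its μ+kσ gate,
    it holds ≥1 library cell, and every required detection event (the cell
    dye plus one per reporter channel, independent Bernoulli at the shared
    detection efficiency) succeeds. Each sorted library cell's genotype
    then survives single-cell PCR independently.
    """
    n = droplets.n_droplets
    thresholds = np.array([gate_threshold(g) for g in gates])
    gated = (activation.signals > thresholds[None, :]).all(axis=1)
    has_lib = droplets.lib_counts > 0
    n_detect = 1 + len(gates)
    detected = (rng.random((n, n_detect)) < detection_efficiency).all(axis=1)
    sorted_mask = gated & has_lib & detected

    in_sorted = np.repeat(sorted_mask, droplets.lib_counts)
    pcr_ok = rng.random(len(droplets.genotypes)) < pcr_success
    recovered_cells = droplets.genotypes[in_sorted & pcr_ok]
    sorted_cells = droplets.genotypes[in_sorted]

    recovered_counts: Dict[str, int] = {}
    rows = []
    loss_rows = []
    encapsulated = np.bincount(droplets.genotypes, minlength=len(labels))
    sorted_by_code = np.bincount(sorted_cells, minlength=len(labels))
    recovered_by_code = np.bincount(recovered_cells, minlength=len(labels))
    for code, label in enumerate(labels):
        if label == BACKGROUND:
            continue
        spiked = spiked_counts.get(label, 0)
        n_enc = int(encapsulated[code])
        n_sorted = int(sorted_by_code[code])
        n_rec = int(recovered_by_code[code])
        recovered_counts[label] = n_rec
        rows.append(
            {
                "run_id": run_id,
                "variant_id": label,
                "abundance_percent": np.nan,  # filled by run_screen from population size
                "copies_spiked": spiked,
                "copies_recovered": n_rec,
            }
        )
        loss_rows.append(
            {
                "variant_id": label,
                "spiked": spiked,
                "not_encapsulated": spiked - n_enc,
                "encapsulated_not_sorted": n_enc - n_sorted,
                "sorted_lost_pcr": n_sorted - n_rec,
                "recovered": n_rec,
            }
        )
    observations = pd.DataFrame(
        rows,
        columns=["run_id", "variant_id", "abundance_percent", "copies_spiked", "copies_recovered"],
    )
    losses = pd.DataFrame(
        loss_rows,
        columns=[
            "variant_id",
            "spiked",
            "not_encapsulated",
            "encapsulated_not_sorted",
            "sorted_lost_pcr",
            "recovered",
        ],
    )
    return SimulatedScreen(
        droplets, activation, sorted_mask, recovered_counts, observations, losses
    )


def run_screen(config: SimConfig) -> SimulatedScreen:
    """Compose population → encapsulation → activation → sort/recover."""
    rng = np.random.default_rng(config.seed)
    population, labels, spiked_counts = build_population(
        config.spikes, config.population_size, rng, config.spike_mode
    )
    n_droplets = config.n_droplets or default_droplet_count(
        config.population_size, config.encapsulation.lambda_library
    )
    droplets = simulate_encapsulation(
        population, config.encapsulation, n_droplets, rng, config.n_channels
    )
    functional_codes = [
        i + 1 for i, s in enumerate(config.spikes) if s.functional
    ]
    activation = simulate_activation(droplets, config.activation, rng, functional_codes)
    screen = simulate_sort_and_recover(
        droplets,
        activation,
        config.gates,
        config.detection_efficiency,
        config.pcr_success,
        rng,
        labels,
        spiked_counts,
        run_id=f"seed{config.seed}",
    )
    # fill in true abundances now that population size is known
    abundance = {
        s.variant_id: 100.0 * spiked_counts[s.variant_id] / config.population_size
        for s in config.spikes
    }
    screen.observations["abundance_percent"] = screen.observations["variant_id"].map(abundance)
    return screen


def run_titration(
    abundances_percent: Sequence[float],
    replicates: int,
    config: SimConfig,
) -> pd.DataFrame:
    """Full-factorial spike titration producing recovery observations.

    Each (abundance, replicate) cell runs an independent screen with a
    child seed spawned deterministically from ``config.seed``; the output
    is the CSV schema the recovery regression consumes.
    """
    if not abundances_percent:
        raise ValueError("need at least one abundance")
    seeds = np.random.SeedSequence(config.seed).spawn(
        len(abundances_percent) * replicates
    )
    rows = []
    i = 0
    for abundance in abundances_percent:
        for rep in range(replicates):
            child = int(seeds[i].generate_state(1)[0] % (2**31 - 1))
            i += 1
            cfg = SimConfig(
                seed=child,
                population_size=config.population_size,
                spikes=(Spike("spike", abundance / 100.0, True),),
                encapsulation=config.encapsulation,
                activation=config.activation,
                detection_efficiency=config.detection_efficiency,
                pcr_success=config.pcr_success,
                gates=config.gates,
                n_droplets=config.n_droplets,
                spike_mode=config.spike_mode,
            )
            screen = run_screen(cfg)
            obs = screen.observations.iloc[0]
            rows.append(
                {
                    "run_id": f"a{abundance}_r{rep}",
                    "abundance_percent": abundance,
                    "copies_spiked": int(obs["copies_spiked"]),
                    "copies_recovered": int(obs["copies_recovered"]),
                }
            )
    return pd.DataFrame(rows)


def analytic_recovery_probability(config: SimConfig) -> float:
    """Closed-form per-copy recovery probability under ideal gates.

    Composition: P(copy encapsulated) × Π over channels of P(≥1 activated
    reporter) × detection^(1+channels) × PCR success. The per-channel
    activation term uses Poisson thinning: 1 - exp(-λ_channel · q) with q
    the per-reporter activation probability in a functional droplet.
    Assumes gates pass every activated channel and multi-copy droplets are
    negligible (valid for rare spikes).
    """
    n_droplets = config.n_droplets or default_droplet_count(
        config.population_size, config.encapsulation.lambda_library
    )
    p_encap = min(
        1.0, n_droplets * config.encapsulation.lambda_library / config.population_size
    )
    lam_chan = config.encapsulation.lambda_reporter / config.n_channels
    act = config.activation
    q = 1.0 - (1.0 - act.p_activate_given_functional) * (1.0 - act.basal_fpr)
    p_channel = -math.expm1(-lam_chan * q)
    return (
        p_encap
        * p_channel**config.n_channels
        * config.detection_efficiency ** (1 + config.n_channels)
        * config.pcr_success
    )


# ---------------------------------------------------------------------------
# Synthetic consensus reads
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_ccs_reads(
    variants: Sequence[BiTEVariant],
    error_model: ReadErrorModel,
    rng: np.random.Generator,
    n_reads: Optional[int] = None,
    weights: Optional[Sequence[float]] = None,
) -> Tuple[List[CCSRead], pd.DataFrame]:
    """Generate synthetic consensus reads from assembled constructs.

    Reads are the variants' DNA with iid substitutions at the configured
    rate, each on a random strand. With ``n_reads`` unset every variant is
    emitted at ``error_model.depth``; otherwise ``n_reads`` reads are
    drawn from ``weights`` (uniform if omitted). Returns the reads plus a
    ground-truth table (read_id, variant label, strand, n_errors).
    """
    for v in variants:
        if not v.dna_seq:
            raise ValueError(f"{v.label}: DNA not assembled")
    if n_reads is None:
        picks = np.repeat(np.arange(len(variants)), error_model.depth)
    else:
        w = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            w = w / w.sum()
        picks = rng.choice(len(variants), size=n_reads, p=w)
    reads: List[CCSRead] = []
    truth_rows = []
    for i, vi in enumerate(picks):
        v = variants[int(vi)]
        seq = _mutate(v.dna_seq, error_model.substitution_rate, rng)
        n_errors = sum(a != b for a, b in zip(seq, v.dna_seq))
        strand = "reverse" if rng.random() < 0.5 else "forward"
        if strand == "reverse":
            seq = str(Seq(seq).reverse_complement())
        read_id = f"read{i:06d}"
        reads.append(CCSRead(read_id, seq))
        truth_rows.append(
            {
                "read_id": read_id,
                "cd19_variant": v.cd19_variant.variant_id,
                "cd3_id": v.cd3.name,
                "linker_id": v.linker.name,
                "orientation": v.orientation.label,
                "strand": strand,
                "n_errors": n_errors,
            }
        )
    return reads, pd.DataFrame(truth_rows)
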