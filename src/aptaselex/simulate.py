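"""Generative model of (toggle) Cell-SELEX rounds.

The simulator emulates an iterative in-vitro selection: a high-diversity
random oligonucleotide pool is repeatedly passed through a negative
selection against non-target cells (acinar tissue), a positive capture on
target cells (pancreatic islets), PCR re-amplification, and finite-depth
sequencing.  A small number of planted "families" (a seed sequence plus a
mutational cloud) carry high latent affinity for the positive selector and
should rise in frequency; everything else is background.  A species toggle
(mouse rounds followed by human rounds) is expressed purely through the
per-cycle selector classes, so cross-reactive families -- those with high
affinity for both mouse and human islets -- are the only ones expected to
survive the full protocol.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; a (config, seed) pair fully reproduces a run.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SELECTOR_CLASSES",
    "CycleSpec",
    "SimConfig",
    "SimTruth",
    "LibraryCollapseError",
    "generate_pool",
    "run_cycle",
    "run_protocol",
    "write_fastq",
    "recovery_config",
    "neutral_config",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
]

#: Selector cell classes a cycle can select for or against.
SELECTOR_CLASSES = ("mouse_islet", "mouse_acinar", "human_islet", "human_acinar")

#: Fixed placeholder constant regions flanking the variable region (the real
#: library's primer-binding sites are proprietary to the original protocol).
DEFAULT_FLANK5 = "TAGGGAAGAGAAGGACATAT"
DEFAULT_FLANK3 = "TTGACTAGTACATGACCACT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class LibraryCollapseError(RuntimeError):
    """Raised when a selection cycle captures zero molecules."""


@dataclass(frozen=True)
class CycleSpec:
    """One selection round.

    Parameters
    ----------
    cycle_id : str
        Label such as ``"M1"`` ... ``"M8"``, ``"M8H1"``, ``"M8H2"``.
    positive_class, negative_class : str
        Selector classes drawn from :data:`SELECTOR_CLASSES`; the pool is
        depleted on the negative class and captured on the positive one.
    stringency : float
        Exponent ``s`` applied to the positive affinity; mapped from the
        wash/input schedule as ``s = 1 + 0.25 x (washes beyond baseline)``.
        ``s = 0`` makes capture affinity-blind (a neutral round).
    depth : int or None
        Per-cycle override of the sequencing depth.
    """

    cycle_id: str
    positive_class: str = "mouse_islet"
    negative_class: str = "mouse_acinar"
    stringency: float = 1.0
    depth: int | None = None

    def __post_init__(self) -> None:
        for cls in (self.positive_class, self.negative_class):
            if cls not in SELECTOR_CLASSES:
                raise ValueError(f"unknown selector class {cls!r}")
        if self.positive_class == self.negative_class:
            raise ValueError("positive_class and negative_class must differ")
        if self.stringency < 0:
            raise ValueError("stringency must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a simulated SELEX protocol."""

    n_background: int = 50_000
    var_len_range: tuple[int, int] = (40, 44)
    n_families: int = 10
    cloud_size: int = 25
    mutation_rate: float = 0.02
    cycles: tuple[CycleSpec, ...] = ()
    depth: int = 200_000
    pcr_gain: float = 100.0
    pcr_noise_sd: float = 0.3
    depletion_strength: float = 0.5
    capture_scale: float = 0.5
    cross_reactive_fraction: float = 0.4
    cross_affinity_cost: float = 0.15
    mutation_penalty: float = 0.1
    pool_size: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.var_len_range
        if not (1 <= lo <= hi <= 200):
            raise ValueError("var_len_range must lie within [1, 200]")
        if self.n_background <= 0 or self.cloud_size <= 0 or self.depth <= 0:
            raise ValueError("n_background, cloud_size and depth must be positive")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        for name in ("mutation_rate", "depletion_strength", "cross_reactive_fraction",
                     "cross_affinity_cost", "mutation_penalty"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.capture_scale <= 1.0:
            raise ValueError("capture_scale must be in (0, 1]")
        if self.pcr_gain <= 0 or self.pcr_noise_sd < 0:
            raise ValueError("pcr_gain must be > 0 and pcr_noise_sd >= 0")
        if self.pool_size < self.depth:
            raise ValueError("pool_size must be at least the sequencing depth")
        if not self.cycles:
            raise ValueError("cycles must be non-empty")


@dataclass
class SimTruth:
    """Ground truth of a simulated pool.

    Attributes
    ----------
    affinity : pandas.DataFrame
        Latent affinity ``a_i in [0, 1]`` per sequence (rows) and selector
        class (columns).
    family_id : pandas.Series
        Planted family index per sequence (``-1`` for background).
    seed_of : dict[int, str]
        Family index -> seed sequence.
    cross_reactive : frozenset[int]
        Family indices with high affinity for both mouse and human islets.
    capture_weights : dict[str, pandas.Series]
        Per-cycle latent capture weight ``w_i = (1 - delta a_neg) kappa a_pos^s``,
        filled in by :func:`run_protocol`.
    """

    affinity: pd.DataFrame
    family_id: pd.Series
    seed_of: dict[int, str]
    cross_reactive: frozenset[int]
    capture_weights: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def sequences(self) -> list[str]:
        return list(self.affinity.index)

    def cross_reactive_seeds(self) -> list[str]:
        return [self.seed_of[f] for f in sorted(self.cross_reactive)]


def _draw_distinct(rng: np.random.Generator, n: int, lo: int, hi: int,
                   taken: set[str], max_retries: int = 100) -> list[str]:
    """Draw ``n`` distinct random sequences, batch-vectorized; collisions
    with ``taken`` (or within the batch) are redrawn up to ``max_retries``
    rounds before failing."""
    out: list[str] = []
    need = n
    for _attempt in range(max_retries):
        if need == 0:
            return out
        lengths = rng.integers(lo, hi + 1, size=need)
        flat = rng.integers(0, 4, size=int(lengths.sum()), dtype=np.int8)
        chars = _BASES[flat].tobytes().decode()
        pos = 0
        for ln in lengths:
            s = chars[pos:pos + int(ln)]
            pos += int(ln)
            if s not in taken:
                taken.add(s)
                out.append(s)
        need = n - len(out)
    raise RuntimeError("could not draw distinct sequences; "
                       "pool too dense for the length range")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Point-mutate each position with probability ``rate``; return (seq, n_subs)."""
    if rate == 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # draw a base != current by offsetting within the 4-letter alphabet
        idx = np.searchsorted(_BASES, arr[hit])
        offs = rng.integers(1, 4, size=n)
        arr[hit] = _BASES[(idx + offs) % 4]
    return arr.tobytes().decode(), n


def generate_pool(config: SimConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[list[str], SimTruth]:
    """Draw the initial sequence pool and its latent ground truth.

    Background sequences get small affinities (Beta(1, 19), mean 0.05) for
    every selector class.  Each planted family seed gets a high affinity
    drawn from U(0.5, 0.9): species-restricted seeds for ``mouse_islet``
    only, cross-reactive seeds a shared (slightly discounted) affinity for
    both islet classes -- mirroring the observation that a mouse-selected
    pool stains mouse but not human islets, so conserved-epitope binders
    are a minority until the species toggle favours them.  Cloud members
    inherit the seed's islet affinities scaled by
    ``(1 - mutation_penalty)^substitutions``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.var_len_range
    taken: set[str] = set()
    background = _draw_distinct(rng, config.n_background, lo, hi, taken)
    seeds = _draw_distinct(rng, config.n_families, lo, hi, taken)

    n_cross = int(round(config.n_families * config.cross_reactive_fraction))
    cross_ids = frozenset(range(n_cross))

    rows: list[str] = list(background)
    aff = rng.beta(1.0, 19.0, size=(config.n_background, len(SELECTOR_CLASSES)))
    aff_rows: list[np.ndarray] = [aff]
    fam: list[int] = [-1] * config.n_background
    seed_of: dict[int, str] = {}

    seen = set(taken)  # background + seeds
    i_mi = SELECTOR_CLASSES.index("mouse_islet")
    i_hi = SELECTOR_CLASSES.index("human_islet")
    for f, seed in enumerate(seeds):
        base = rng.uniform(0.5, 0.9)
        seed_aff = rng.beta(1.0, 19.0, size=len(SELECTOR_CLASSES))
        if f in cross_ids:
            shared = base * (1.0 - config.cross_affinity_cost)
            seed_aff[i_mi] = shared
            seed_aff[i_hi] = shared
        else:
            seed_aff[i_mi] = base
        fam_rows = [seed_aff]
        rows.append(seed)
        fam.append(f)
        for _ in range(config.cloud_size - 1):
            m, nsub = _mutate(rng, seed, config.mutation_rate)
            if m in seen:
                continue  # identical to the seed or an existing sequence: merged
            scale = (1.0 - config.mutation_penalty) ** nsub
            a = seed_aff.copy()
            a[i_mi] *= scale
            a[i_hi] *= scale
            rows.append(m)
            fam.append(f)
            fam_rows.append(a)
            seen.add(m)
        seed_of[f] = seed
        aff_rows.append(np.vstack(fam_rows))

    affinity = pd.DataFrame(np.clip(np.vstack(aff_rows), 0.0, 1.0),
                            index=rows, columns=list(SELECTOR_CLASSES))
    truth = SimTruth(
        affinity=affinity,
        family_id=pd.Series(fam, index=rows, name="family_id"),
        seed_of=seed_of,
        cross_reactive=cross_ids,
    )
    return rows, truth


def capture_weight(truth: SimTruth, spec: CycleSpec, config: SimConfig) -> pd.Series:
    """Latent per-sequence capture weight for one cycle."""
    a_pos = truth.affinity[spec.positive_class].to_numpy()
    a_neg = truth.affinity[spec.negative_class].to_numpy()
    w = ((1.0 - config.depletion_strength * a_neg)
         * config.capture_scale * np.power(a_pos, spec.stringency))
    return pd.Series(w, index=truth.affinity.index, name=spec.cycle_id)


def _select_and_amplify(counts: pd.Series, spec: CycleSpec, truth: SimTruth,
                        config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Negative selection -> capture -> PCR -> input renormalization.

    Returns the post-amplification molecular pool, downsampled to
    ``config.pool_size`` molecules (each round feeds on a fixed input
    amount, as in the bench protocol's fixed pmol input per cycle).
    """
    counts = counts[counts > 0]
    if counts.empty:
        raise LibraryCollapseError(f"cycle {spec.cycle_id}: empty input library")
    seqs = counts.index
    c = counts.to_numpy(dtype=np.int64)
    a_pos = truth.affinity.loc[seqs, spec.positive_class].to_numpy()
    a_neg = truth.affinity.loc[seqs, spec.negative_class].to_numpy()

    p_survive = np.clip(1.0 - config.depletion_strength * a_neg, 0.0, 1.0)
    survivors = rng.binomial(c, p_survive)
    p_capture = np.clip(config.capture_scale * np.power(a_pos, spec.stringency), 0.0, 1.0)
    captured = rng.binomial(survivors, p_capture)
    if captured.sum() == 0:
        raise LibraryCollapseError(
            f"cycle {spec.cycle_id}: no molecules captured (library collapsed)")

    if config.pcr_noise_sd > 0:
        mu = math.log(config.pcr_gain) - 0.5 * config.pcr_noise_sd ** 2
        gain = rng.lognormal(mu, config.pcr_noise_sd, size=captured.size)
    else:
        gain = np.full(captured.size, config.pcr_gain)
    amplified = np.rint(captured * gain)
    total = amplified.sum()
    if total == 0:
        raise LibraryCollapseError(f"cycle {spec.cycle_id}: amplification yielded nothing")
    if total > config.pool_size:
        pool = rng.multinomial(config.pool_size, amplified / total)
    else:
        pool = amplified.astype(np.int64)
    kept = pool > 0
    return pd.Series(pool[kept], index=seqs[kept], name=spec.cycle_id)


def _sequence_aliquot(pool: pd.Series, spec: CycleSpec, config: SimConfig,
                      rng: np.random.Generator) -> pd.Series:
    depth = spec.depth if spec.depth is not None else config.depth
    out = rng.multinomial(depth, pool.to_numpy() / pool.sum())
    kept = out > 0
    return pd.Series(out[kept], index=pool.index[kept], name=spec.cycle_id)


def run_cycle(counts: pd.Series, spec: CycleSpec, truth: SimTruth,
              config: SimConfig, rng: np.random.Generator,
              return_pool: bool = False):
    """Push a count vector through one selection round.

    Chain: negative-selection survival ``Binomial(c, 1 - delta a_neg)`` ->
    capture ``Binomial(., kappa a_pos^s)`` -> per-sequence lognormal PCR
    gain (mean ``pcr_gain``, log-sd ``pcr_noise_sd``) -> multinomial
    sequencing draw of ``depth`` reads.  Returns the sequenced sample; with
    ``return_pool`` also the carried molecular pool (the sequencing draw is
    an aliquot and does not bottleneck the selection itself).
    """
    pool = _select_and_amplify(counts, spec, truth, config, rng)
    sample = _sequence_aliquot(pool, spec, config, rng)
    return (sample, pool) if return_pool else sample


def run_protocol(config: SimConfig, protocol_seed: int | None = None):
    """Run every configured cycle; return (list of CycleLibrary, SimTruth).

    The naive pool starts at ``pool_size`` molecules spread uniformly over
    the generated sequences; each cycle consumes the previous cycle's
    molecular pool, while the emitted CycleLibrary holds that cycle's
    ``depth``-read sequencing aliquot.  ``protocol_seed`` re-seeds only the
    selection/sequencing randomness, so two values share one sequence
    universe (the pool is always drawn from ``config.seed``).
    """
    from .reads import CycleLibrary  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    pool_seqs, truth = generate_pool(config, rng)
    if protocol_seed is not None:
        rng = np.random.default_rng(protocol_seed)
    n = len(pool_seqs)
    pool = pd.Series(rng.multinomial(config.pool_size, np.full(n, 1.0 / n)),
                     index=pool_seqs)

    libraries = []
    for spec in config.cycles:
        truth.capture_weights[spec.cycle_id] = capture_weight(truth, spec, config)
        sample, pool = run_cycle(pool, spec, truth, config, rng, return_pool=True)
        depth = spec.depth if spec.depth is not None else config.depth
        libraries.append(CycleLibrary(
            cycle_id=spec.cycle_id,
            counts=dict(sorted(sample.items())),
            total_reads=depth,
            extracted_reads=int(sample.sum()),
        ))
    return libraries, truth


def write_fastq(lib, flank5: str = DEFAULT_FLANK5, flank3: str = DEFAULT_FLANK3,
                path=None) -> None:
    """Write a cycle library as FASTQ: each read is flank5+variable+flank3.

    Records are emitted deterministically, sorted by sequence then repeat
    index, with a constant Phred+33 quality string (Q40).  A ``.gz`` suffix
    selects gzip output.  An empty library yields a valid empty file.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for seq in sorted(lib.counts):
            read = f"{flank5}{seq}{flank3}"
            qual = "I" * len(read)
            for j in range(lib.counts[seq]):
                fh.write(f"@{lib.cycle_id}:{seq[:8]}:{j}\n{read}\n+\n{qual}\n")


def _toggle_cycles(n_mouse: int = 8, n_human: int = 2) -> tuple[CycleSpec, ...]:
    """Mouse cycles M1..Mn then human toggle cycles, with the published
    wash-derived stringency schedule (3 washes cycles 1-4, 4 in 5-6, 6 in
    7-8 and the human rounds)."""
    def s_for(i: int) -> float:
        if i <= 4:
            return 1.0
        if i <= 6:
            return 1.25
        return 1.75
    cycles = [CycleSpec(f"M{i}", "mouse_islet", "mouse_acinar", s_for(i))
              for i in range(1, n_mouse + 1)]
    cycles += [CycleSpec(f"M{n_mouse}H{j}", "human_islet", "human_acinar", 1.75)
               for j in range(1, n_human + 1)]
    return tuple(cycles)


def recovery_config(seed: int = 0, **overrides) -> SimConfig:
    """Default recovery scenario: 5e4 background sequences, 10 planted
    families (cloud 25, mutation 0.02), 4 cross-reactive, 8 mouse + 2 human
    cycles at depth 2e5."""
    cfg = SimConfig(cycles=_toggle_cycles(), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def neutral_config(seed: int = 0, n_background: int = 1_000_000,
                   depth: int = 20_000, n_cycles: int = 3) -> SimConfig:
    """Selection-free protocol (s=0, delta=0, no PCR noise) whose depth is
    far below the pool diversity, so complexity should stay near 100%."""
    cycles = tuple(CycleSpec(f"C{i}", stringency=0.0) for i in range(1, n_cycles + 1))
    return SimConfig(n_background=n_background, n_families=0, cycles=cycles,
                     depth=depth, pcr_noise_sd=0.0, depletion_strength=0.0,
                     seed=seed)
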