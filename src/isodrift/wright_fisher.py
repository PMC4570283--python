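"""Forward-time single-locus Wright-Fisher simulation with selection.

Each generation applies a deterministic selection update followed by
binomial resampling of the 2*Ne allele copies.  The default fitness scheme
is genic (multiplicative per allele copy): genotype fitnesses
``1 : (1+s) : (1+s)^2``, giving the update ``p* = p(1+s)/(1+s*p)``; an
optional dominance coefficient ``h`` switches to ``1 : 1+hs : 1+s``.

The two bundled scenarios reproduce the drift-vs-selection contrasts used to
interpret highly differentiated variants in a drifted isolate: the lactase
(LCT) regulatory variant under pure drift, and the ACTN3 stop-gain variant
with and without a selective advantage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "TrajectoryEnsemble", "wf_step", "run_ensemble",
           "scenario_lct", "scenario_actn3"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a Wright-Fisher ensemble run.

    Defaults follow the drifted-isolate setting: diploid Ne = 2,471 (the
    LD-based point estimate; 95% CI presets 2,319 and 2,603), 500 generations
    recorded every 50, 1,000 replicates, neutral unless ``s`` is set.
    """

    ne: int = 2471
    s: float = 0.0
    p0: float = 0.5
    n_generations: int = 500
    record_interval: int = 50
    n_replicates: int = 1000
    threshold: float | None = None
    dominance: float | None = None  # None = genic selection
    seed: int = 0

    NE_CI_LOW = 2319
    NE_CI_HIGH = 2603

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_generations % self.record_interval:
            raise ValueError("record_interval must divide n_generations")


@dataclass
class TrajectoryEnsemble:
    """Replicate x time-grid derived-allele frequencies plus summaries."""

    config: SimConfig
    generations: np.ndarray  # recording grid incl. generation 0
    frequencies: np.ndarray  # (n_replicates, len(generations))
    first_hit_generation: int | None = None  # first recorded gen any replicate >= threshold
    ever_reached: np.ndarray | None = None  # per-replicate, tracked every generation
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        term = self.frequencies[:, -1]
        cfg = self.config
        self.summary.setdefault("fraction_fixed_derived", float((term == 1.0).mean()))
        self.summary.setdefault("fraction_fixed_ancestral", float((term == 0.0).mean()))
        if cfg.threshold is not None:
            self.summary.setdefault(
                "fraction_terminal_at_threshold", float((term >= cfg.threshold).mean())
            )
            if self.ever_reached is not None:
                self.summary.setdefault(
                    "fraction_ever_at_threshold", float(self.ever_reached.mean())
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frequencies,
            columns=[f"gen_{g}" for g in self.generations],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="replicate")


def wf_step(
    p: np.ndarray | float,
    ne: int,
    s: float = 0.0,
    h: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """One Wright-Fisher generation: selection then binomial drift.

    Vectorised over an array of replicate frequencies.  Frequencies 0 and 1
    are absorbing.
    """
    rng = rng or np.random.default_rng()
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    p_sel = selection_update(p_arr, s, h)
    out = rng.binomial(2 * ne, p_sel) / (2.0 * ne)
    return out if np.ndim(p) else float(out[0])


def selection_update(p: np.ndarray, s: float, h: float | None = None) -> np.ndarray:
    """Deterministic post-selection frequency.

    Genic (``h=None``): ``p* = p(1+s)/(1+s*p)``.  With dominance ``h``:
    genotype fitnesses ``1 : 1+hs : 1+s``.
    """
    p = np.asarray(p, dtype=float)
    if s == 0.0:
        return p
    q = 1.0 - p
    if h is None:
        return p * (1.0 + s) / (1.0 + s * p)
    w_bar = p * p * (1.0 + s) + 2.0 * p * q * (1.0 + h * s) + q * q
    return (p * p * (1.0 + s) + p * q * (1.0 + h * s)) / w_bar


def run_ensemble(config: SimConfig) -> TrajectoryEnsemble:
    """Run ``n_replicates`` independent trajectories from ``p0``.

    Frequencies are recorded on the grid {0, record_interval, ...,
    n_generations}; threshold attainment is additionally tracked every
    generation for the "ever reached" summary.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.arange(0, config.n_generations + 1, config.record_interval)
    freqs = np.empty((config.n_replicates, grid.size))
    p = np.full(config.n_replicates, config.p0)
    freqs[:, 0] = p
    ever = None
    if config.threshold is not None:
        ever = p >= config.threshold
    first_hit = 0 if (ever is not None and ever.any()) else None
    col = 1
    for gen in range(1, config.n_generations + 1):
        p = wf_step(p, config.ne, config.s, config.dominance, rng)
        if ever is not None:
            ever |= p >= config.threshold
        if gen % config.record_interval == 0:
            freqs[:, col] = p
            if (
                first_hit is None
                and config.threshold is not None
                and (p >= config.threshold).any()
            ):
                first_hit = gen
            col += 1
    return TrajectoryEnsemble(
        config=config,
        generations=grid,
        frequencies=freqs,
        first_hit_generation=first_hit,
        ever_reached=ever,
    )


def scenario_lct(**overrides) -> TrajectoryEnsemble:
    """Neutral drift scenario for the lactase-persistence variant.

    The derived (lactase-persistence) allele starts at its regional average
    frequency of 0.29; the question is how often pure drift fixes the
    ancestral allele (derived frequency 0) within 500 generations at
    Ne = 2,471.  The key summary is ``percent_ancestral_fixed``.
    """
    cfg = replace(SimConfig(p0=0.29, s=0.0), **overrides)
    ens = run_ensemble(cfg)
    ens.summary["percent_ancestral_fixed"] = 100.0 * ens.summary["fraction_fixed_ancestral"]
    return ens


def scenario_actn3(
    seed: int = 0, dominance: float | None = 0.0, **overrides
) -> dict[str, TrajectoryEnsemble]:
    """Drift-vs-selection contrast for the ACTN3 stop-gain variant.

    Starting from the regional average derived frequency of 0.47, a neutral
    arm and a selected arm (s = 0.01) each run 500 generations; the summary
    per arm is the percentage of replicates whose terminal frequency reaches
    the isolate's observed 0.93, plus the "ever reached" variant and the
    first recorded generation at which any replicate crosses it.

    The selected arm defaults to a recessive advantage of the derived allele
    (genotype fitnesses 1 : 1 : 1+s, ``dominance=0``): the stop-gain only
    changes the protein dose in derived homozygotes, and only this scheme
    crosses the observed frequency on the several-hundred-generation
    timescale the trajectory data show (genic selection at s = 0.01 crosses
    deterministically by generation ~270 and fixes in essentially every
    replicate).  Pass ``dominance=None`` for the genic scheme.
    """
    arms = {}
    for name, s in (("neutral", 0.0), ("selected", 0.01)):
        cfg = replace(
            SimConfig(
                p0=0.47,
                threshold=0.93,
                s=s,
                dominance=dominance,
                seed=seed + (0 if s == 0 else 1),
            ),
            **overrides,
        )
        ens = run_ensemble(cfg)
        ens.summary["percent_terminal_at_threshold"] = (
            100.0 * ens.summary["fraction_terminal_at_threshold"]
        )
        ens.summary["percent_ever_at_threshold"] = (
            100.0 * ens.summary["fraction_ever_at_threshold"]
        )
        arms[name] = ens
    return arms
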