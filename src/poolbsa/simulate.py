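"""Synthetic multi-population pooled-sequencing experiments with known truth.

The generator emulates a bulked-segregant design: for each of several wild
populations, one control pool and one phenotype-selected pool of N females
are sequenced to finite depth. Population structure follows the
Balding–Nichols model (per-population control frequencies Beta-distributed
around an ancestral frequency with differentiation parameter F). Causal
SNPs shift the selected pool's true frequency by an additive effect delta
on the arcsine-square-root scale; the effect pattern follows one of four
scenarios matching the nested test models:

* ``null``     — no SNP has any effect,
* ``parallel`` — a single shared delta in every population,
* ``group``    — one delta per exposure group (high / low),
* ``free``     — an arbitrary per-population delta vector.

Read counts are produced by two-stage sampling: 2N chromosomes drawn
binomially from the population frequency, then a Poisson-distributed
number of reads (truncated at >= 1) drawn binomially from the pool
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Pool, PoolCounts, SITE_COLUMNS, StudyDesign

#: Default populations: two high-exposure and two low-exposure sites.
DEFAULT_POPULATIONS: tuple[tuple[str, str], ...] = (
    ("BBM", "high"),
    ("GPO", "high"),
    ("RFF", "low"),
    ("DBF", "low"),
)

ARMS = ("2L", "2R", "3L", "3R", "X")
_SPACING = 200  # bp between simulated SNPs on an arm

EFFECT_MODELS = ("null", "parallel", "group", "free")


@dataclass
class SimScenario:
    """Parameters of one synthetic pooled-sequencing experiment.

    Defaults mirror the study design this package targets: 4 populations
    x 2 pools of 150 females, ~130x mean coverage per pool, weak structure
    (F ~ 0.005), ancestral frequencies drawn from Uniform(0.05, 0.95) so
    that most sites pass the minor-allele-frequency filter.
    """

    n_snps: int
    populations: Sequence[tuple[str, str]] = DEFAULT_POPULATIONS
    pool_size: int = 150
    mean_depth: float = 130.0
    fst_target: float = 0.005
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    effect_model: str = "null"
    delta: float | tuple[float, float] | Sequence[float] = 0.0
    causal_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in [0, 1]")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(
                f"effect_model must be one of {EFFECT_MODELS}, "
                f"got {self.effect_model!r}"
            )
        self.resolve_deltas()  # validates delta shape

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def resolve_deltas(self) -> np.ndarray:
        """Per-population effect vector implied by effect_model and delta."""
        groups = np.array([g for _, g in self.populations])
        if self.effect_model == "null":
            return np.zeros(self.n_pops)
        if self.effect_model == "parallel":
            if np.ndim(self.delta) != 0:
                raise ValueError("parallel model needs a scalar delta")
            return np.full(self.n_pops, float(self.delta))
        if self.effect_model == "group":
            if np.ndim(self.delta) != 1 or len(self.delta) != 2:
                raise ValueError(
                    "group model needs delta = (delta_high, delta_low)"
                )
            d_high, d_low = (float(d) for d in self.delta)
            return np.where(groups == "high", d_high, d_low)
        # free
        if np.ndim(self.delta) != 1 or len(self.delta) != self.n_pops:
            raise ValueError(
                "free model needs one delta per population "
                f"({self.n_pops} populations)"
            )
        return np.asarray(self.delta, dtype=float)

    def design(self) -> StudyDesign:
        pools = []
        for pop, _ in self.populations:
            for cond in ("control", "selected"):
                pools.append(
                    Pool(f"{pop}_{cond}", pop, cond, self.pool_size)
                )
        return StudyDesign(list(self.populations), pools)


def simulate_founder_freqs(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral and per-population true control frequencies.

    Returns ``(p_a, P)`` where ``p_a`` has shape (n_snps,) and ``P`` has
    shape (n_snps, n_pops). Under Balding–Nichols, each population's
    frequency is Beta(p_a (1-F)/F, (1-p_a)(1-F)/F); when F = 0 every
    population equals the ancestral frequency exactly.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.ancestral_freq_range
    p_a = rng.uniform(lo, hi, size=scenario.n_snps)
    F = scenario.fst_target
    if F == 0.0:
        P = np.repeat(p_a[:, None], scenario.n_pops, axis=1)
    else:
        scale = (1.0 - F) / F
        P = rng.beta(
            p_a[:, None] * scale,
            (1.0 - p_a[:, None]) * scale,
            size=(scenario.n_snps, scenario.n_pops),
        )
    return p_a, P


def apply_shift(p_ctrl, delta):
    """Shift a frequency by ``delta`` radians on the arcsine-sqrt scale.

    Returns sin^2(clamp(arcsin(sqrt(p_ctrl)) + delta, 0, pi/2)); the clamp
    keeps the result a valid frequency at the boundaries.
    """
    z = np.arcsin(np.sqrt(p_ctrl)) + delta
    return np.square(np.sin(np.clip(z, 0.0, np.pi / 2)))


def _truncated_poisson(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    depth = rng.poisson(mean, size=size)
    while True:
        zero = depth == 0
        if not zero.any():
            return depth
        depth[zero] = rng.poisson(mean, size=int(zero.sum()))


def sample_pool_reads(
    p_true,
    pool_size: int,
    mean_depth: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage read sampling for one pool.

    Chromosomes: k ~ Binomial(2 * pool_size, p_true); the pool frequency is
    k / (2 * pool_size). Depth ~ Poisson(mean_depth) truncated at >= 1;
    reference reads ~ Binomial(depth, pool frequency).
    """
    p_true = np.asarray(p_true, dtype=float)
    k = rng.binomial(2 * pool_size, p_true)
    pool_freq = k / (2.0 * pool_size)
    depth = _truncated_poisson(rng, mean_depth, p_true.shape)
    ref = rng.binomial(depth, pool_freq)
    return ref, depth


def _positions(n_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Spread SNPs contiguously across the five major arms."""
    per_arm = int(np.ceil(n_snps / len(ARMS)))
    chroms = np.repeat(ARMS, per_arm)[:n_snps]
    offsets = np.tile(np.arange(per_arm), len(ARMS))[:n_snps]
    pos = 1000 + offsets * _SPACING
    return chroms, pos


def simulate_experiment(
    scenario: SimScenario,
) -> tuple[PoolCounts, StudyDesign, pd.DataFrame]:
    """Generate counts, design, and a row-aligned truth table.

    The truth table has one row per SNP: ancestral frequency ``p_a``,
    per-population control frequency ``p_<pop>``, the ``causal`` flag and
    the realized per-population effect ``delta_<pop>`` (zero everywhere
    for non-causal SNPs). Identical scenarios and seeds give identical
    output.
    """
    rng = np.random.default_rng(scenario.seed)
    design = scenario.design()
    p_a, P = simulate_founder_freqs(scenario, rng)

    n = scenario.n_snps
    causal = np.zeros(n, dtype=bool)
    deltas = np.zeros((n, scenario.n_pops))
    n_causal = int(round(scenario.causal_fraction * n))
    if scenario.effect_model != "null" and n_causal > 0:
        idx = rng.choice(n, size=n_causal, replace=False)
        causal[idx] = True
        deltas[idx] = scenario.resolve_deltas()

    chroms, pos = _positions(n)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "A", "alt": "T"}
    )
    for j, (pop, _) in enumerate(scenario.populations):
        for cond in ("control", "selected"):
            p_true = P[:, j] if cond == "control" else apply_shift(
                P[:, j], deltas[:, j]
            )
            ref, depth = sample_pool_reads(
                p_true, scenario.pool_size, scenario.mean_depth, rng
            )
            sites[f"{pop}_{cond}:ref"] = ref
            sites[f"{pop}_{cond}:depth"] = depth

    truth = pd.DataFrame({"chrom": chroms, "pos": pos, "p_ancestral": p_a})
    for j, (pop, _) in enumerate(scenario.populations):
        truth[f"p_{pop}"] = P[:, j]
    truth["causal"] = causal
    for j, (pop, _) in enumerate(scenario.populations):
        truth[f"delta_{pop}"] = deltas[:, j]

    return PoolCounts(sites, design.pool_ids), design, truth


def scenario_from_dict(doc: dict) -> SimScenario:
    """Build a scenario from a parsed YAML/JSON mapping.

    ``delta`` may be a scalar, a ``{high: x, low: y}`` mapping (group
    model), a ``{pop_id: x, ...}`` mapping (free model), or a list.
    """
    doc = dict(doc)
    pops = doc.get("populations")
    if pops is not None:
        doc["populations"] = [
            (str(p["id"]), str(p["exposure_group"])) for p in pops
        ]
    delta = doc.get("delta")
    if isinstance(delta, dict):
        if set(delta) == {"high", "low"}:
            doc["delta"] = (float(delta["high"]), float(delta["low"]))
        else:
            pop_ids = [p for p, _ in doc.get("populations", DEFAULT_POPULATIONS)]
            try:
                doc["delta"] = [float(delta[p]) for p in pop_ids]
            except KeyError as exc:
                raise ValueError(
                    f"delta mapping missing population {exc}"
                ) from exc
    elif isinstance(delta, list):
        doc["delta"] = [float(d) for d in delta]
    if "ancestral_freq_range" in doc:
        doc["ancestral_freq_range"] = tuple(doc["ancestral_freq_range"])
    return SimScenario(**doc)
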