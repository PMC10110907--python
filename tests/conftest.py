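import numpy as np
import pandas as pd
import pytest

from poolbsa import Pool, PoolCounts, StudyDesign, run_bsa
from poolbsa.simulate import SimScenario, simulate_experiment

POPULATIONS = [("BBM", "high"), ("GPO", "high"), ("RFF", "low"), ("DBF", "low")]
POOL_IDS = [f"{pop}_{cond}" for pop, _ in POPULATIONS
            for cond in ("control", "selected")]


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    pools = [
        Pool(f"{pop}_{cond}", pop, cond, 150)
        for pop, _ in POPULATIONS
        for cond in ("control", "selected")
    ]
    return StudyDesign(list(POPULATIONS), pools)


def make_counts(rows: list[dict]) -> PoolCounts:
    """Build a PoolCounts from row dicts; unspecified pools get 60/120."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "chrom": row.get("chrom", "2L"),
            "pos": row.get("pos", 1000 + 200 * i),
            "ref": "A",
            "alt": "T",
        }
        for pid in POOL_IDS:
            ref, depth = row.get(pid, (60, 120))
            rec[f"{pid}:ref"] = ref
            rec[f"{pid}:depth"] = depth
        records.append(rec)
    columns = ["chrom", "pos", "ref", "alt"] + [
        f"{pid}:{suffix}" for pid in POOL_IDS for suffix in ("ref", "depth")
    ]
    frame = pd.DataFrame(records, columns=columns)
    if not records:
        frame = frame.astype({"pos": np.int64})
    return PoolCounts(frame, list(POOL_IDS))


@pytest.fixture
def toy_counts() -> PoolCounts:
    """Six-row filter fixture: exactly rows A and E survive the defaults.

    A ok; B off-arm; C under-depth in one pool; D folded control MAF 0.03
    everywhere; E ok; F zero depth in one pool.
    """
    high_freq = {f"{pop}_control": (116, 120) for pop, _ in POPULATIONS}
    return make_counts(
        [
            {"chrom": "2L", "pos": 1000},                      # A
            {"chrom": "4", "pos": 2000},                       # B
            {"chrom": "2R", "pos": 3000,
             "BBM_selected": (45, 90)},                        # C
            {"chrom": "3L", "pos": 4000, **high_freq},         # D
            {"chrom": "X", "pos": 5000},                       # E
            {"chrom": "3R", "pos": 6000,
             "GPO_control": (0, 0)},                           # F
        ]
    )


# -- session-scoped simulation runs shared by acceptance + unit tests -------


@pytest.fixture(scope="session")
def null_run():
    """20k-SNP null simulation at the study conditions, fully analysed."""
    scenario = SimScenario(n_snps=20_000, seed=42)
    counts, sim_design, truth = simulate_experiment(scenario)
    return run_bsa(counts, sim_design), truth


@pytest.fixture(scope="session")
def mixture_run():
    """95% null / 5% causal parallel shifts of 0.3 radians, 20k SNPs."""
    scenario = SimScenario(
        n_snps=20_000, effect_model="parallel", delta=0.3,
        causal_fraction=0.05, seed=11,
    )
    counts, sim_design, truth = simulate_experiment(scenario)
    return run_bsa(counts, sim_design), truth
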