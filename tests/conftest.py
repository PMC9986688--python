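import numpy as np
import pytest

from prsalpha import (
    SimConfig,
    VarianceParams,
    constrain_baseline,
    load_incidence,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def params():
    return VarianceParams()


@pytest.fixture(scope="session")
def incidence():
    return load_incidence()


@pytest.fixture(scope="session")
def baseline(incidence, params):
    return constrain_baseline(incidence, params)


@pytest.fixture(scope="session")
def small_cohort(baseline):
    """50-record cohort simulated at alpha=0.44 for likelihood cross-checks."""
    cfg = SimConfig(n_cases=25, n_controls=25, true_alpha=0.44, seed=7)
    return simulate_cohort(cfg, baseline=baseline)


@pytest.fixture(scope="session")
def medium_cohort(baseline):
    """Mid-sized cohort at alpha=0.44 for regression-based estimators."""
    cfg = SimConfig(n_cases=1200, n_controls=1800, true_alpha=0.44, seed=11)
    return simulate_cohort(cfg, baseline=baseline)


@pytest.fixture(scope="session")
def null_cohort(baseline):
    """Cohort simulated with alpha=0: the PRS carries no risk information."""
    cfg = SimConfig(n_cases=1200, n_controls=1800, true_alpha=0.0, seed=13)
    return simulate_cohort(cfg, baseline=baseline)


def make_weight_lines(n_variants, include_chek2_pair=True, seed=0, name="SYNTH"):
    """Synthetic weight-file lines with GRCh37-style keys.

    Includes the two real chromosome-22 CHEK2*1100delC-linked keys when
    requested; all other variants are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    lines = [f"# name={name}", "variant\teffect_allele\tweight"]
    keys = []
    if include_chek2_pair:
        keys += ["22_29203724_C_T", "22_29551872_A_G"]
    pos = 10_000
    while len(keys) < n_variants:
        pos += int(rng.integers(500, 5000))
        chrom = int(rng.integers(1, 23))
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        keys.append(f"{chrom}_{pos}_{ref}_{alt}")
    for k in keys[:n_variants]:
        ref, alt = k.split("_")[2:]
        allele = alt if rng.random() < 0.9 else ref
        lines.append(f"{k}\t{allele}\t{rng.normal(0, 0.05):.6f}")
    return lines


@pytest.fixture()
def weight_file_313(tmp_path):
    p = tmp_path / "prs313_synthetic.tsv"
    p.write_text("\n".join(make_weight_lines(313, name="PRS313_SYNTH")) + "\n")
    return p
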