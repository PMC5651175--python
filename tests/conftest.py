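import numpy as np
import pandas as pd
import pytest

from esomix.io_formats import ArmDefinition, OmicsMatrix, VariantCall
from esomix.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 20+20-sample cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(
        n_samples_per_subtype={"S1": 20, "S2": 20}, seed=11))


@pytest.fixture
def toy_arm():
    return ArmDefinition("1p", "1", 0, 100_000_000)


def make_variant(**overrides) -> VariantCall:
    base = dict(
        sample_id="T1", chromosome="1", position=100, ref="C", alt="T",
        t_ref_count=55, t_alt_count=5, n_ref_count=50, n_alt_count=0,
        caller="A",
    )
    base.update(overrides)
    return VariantCall(**base)


def random_variant(rng: np.random.Generator, sample="T1", caller="A",
                   position=None) -> VariantCall:
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    has_orient = rng.random() < 0.5
    t_alt = int(rng.integers(0, 30))
    f1r2 = int(rng.integers(0, t_alt + 1)) if has_orient else None
    return VariantCall(
        sample_id=sample,
        chromosome=str(rng.integers(1, 23)),
        position=int(rng.integers(0, 10_000)) if position is None else position,
        ref=str(ref), alt=str(alt),
        t_ref_count=int(rng.integers(0, 200)),
        t_alt_count=t_alt,
        n_ref_count=int(rng.integers(0, 60)),
        n_alt_count=int(rng.integers(0, 4)),
        caller=caller,
        alt_f1r2=f1r2,
        alt_f2r1=(t_alt - f1r2) if has_orient else None,
    )


@pytest.fixture
def expr_matrix_factory():
    def make(n_genes=100, n_samples=20, seed=0, scale="RPKM"):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(np.log(20), 1.0, size=(n_genes, n_samples))
        return OmicsMatrix(
            pd.DataFrame(values,
                         index=[f"G{i:04d}" for i in range(n_genes)],
                         columns=[f"S{i:03d}" for i in range(n_samples)]),
            scale)
    return make
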