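import numpy as np
import pytest

from refstab import CtTable


@pytest.fixture
def abc_table() -> CtTable:
    """Hand-worked 3-gene x 4-sample fixture used across method tests.

    B is A shifted by +2 cycles (so their pairwise SD is 0); C wobbles
    around A with SD(C-A) = sqrt(0.32/3) = 0.32660.
    """
    return CtTable(
        genes=["A", "B", "C"],
        samples=["s1", "s2", "s3", "s4"],
        ct=np.array([
            [20.0, 20.1, 19.9, 20.0],
            [22.0, 22.1, 21.9, 22.0],
            [25.0, 25.5, 24.5, 25.0],
        ]),
        groups={s: "g1" for s in ["s1", "s2", "s3", "s4"]},
    )


def random_table(rng: np.random.Generator, n_genes: int = 5, n_samples: int = 8,
                 n_groups: int = 2) -> CtTable:
    """Random valid Ct table for property tests."""
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    ct = rng.uniform(15.0, 30.0, size=(n_genes, n_samples))
    groups = {s: f"grp{j % n_groups}" for j, s in enumerate(samples)}
    return CtTable(genes=genes, samples=samples, ct=ct, groups=groups)
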