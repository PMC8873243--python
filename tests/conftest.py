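import numpy as np
import pytest

from netperturb.interactome import (
    InterfaceRecord,
    ResidueRsaRecord,
    StructurallyResolvedNetwork,
    build_network,
)
from netperturb.synthetic import PlantedModel, generate_bundle


def net_from_dicts(
    interfaces: dict[tuple[str, str], tuple[set, set]],
    rsa: dict[tuple[str, int], float] | None = None,
) -> StructurallyResolvedNetwork:
    """Hand-build a network: ``{(a, b): (positions_on_a, positions_on_b)}``
    plus optional single-chain RSA values per (protein, position)."""
    records = []
    for (a, b), (pos_a, pos_b) in interfaces.items():
        records.extend(InterfaceRecord(a, b, p) for p in sorted(pos_a))
        records.extend(InterfaceRecord(b, a, p) for p in sorted(pos_b))
    rsa_records = [
        ResidueRsaRecord(prot, "A", pos, val)
        for (prot, pos), val in (rsa or {}).items()
    ]
    return build_network(records, rsa_records)


@pytest.fixture(scope="session")
def small_bundle():
    """50-protein bundle shared by fast integration tests."""
    return generate_bundle(n_proteins=50, n_mutations=200, seed=1)


@pytest.fixture(scope="session")
def recovery_bundle():
    """The planted-signal recovery bundle: 300 proteins, 2000 mutations."""
    return generate_bundle(
        n_proteins=300,
        n_mutations=2000,
        model=PlantedModel(beta0=-1.0, beta_deg=1.5, beta_iface=2.0, beta_core=1.0, seed=8),
        seed=7,
    )


@pytest.fixture(scope="session")
def recovery_dataset(recovery_bundle):
    from netperturb.features import featurize
    from netperturb.model import LabeledDataset

    result = featurize(recovery_bundle.network, recovery_bundle.mutations)
    return LabeledDataset.from_featurize(result)
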