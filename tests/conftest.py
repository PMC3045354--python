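import numpy as np
import pytest

from salicurves import ActivityTable, SimilarityMatrix

# Twenty public drug-like molecules; exercises the fingerprint path
# end-to-end without shipping any data files.
DRUG_SMILES = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "naproxen": "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "diazepam": "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "nicotine": "CN1CCCC1c1cccnc1",
    "sulfamethoxazole": "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",
    "metoprolol": "COCCc1ccc(OCC(O)CNC(C)C)cc1",
    "lidocaine": "CCN(CC)CC(=O)Nc1c(C)cccc1C",
    "chlorpromazine": "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "fluoxetine": "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",
    "cimetidine": "CC1=C(N=CN1)CSCCNC(=NC)NC#N",
    "ketoprofen": "CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1",
    "indomethacin": "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",
    "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "salbutamol": "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
}


@pytest.fixture(scope="session")
def drug_smiles():
    return dict(DRUG_SMILES)


@pytest.fixture
def worked_example():
    """Three compounds with known SALI curve: S=1/3 on [0,1/3], 0 on (1/3,0.4],
    1 on (0.4,1]; SCI = 32/45 ~ 0.7111."""
    ids = ["a", "b", "c"]
    sim = SimilarityMatrix(
        ids, np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]])
    )
    observed = np.array([0.0, 1.0, 3.0])
    predicted = np.array([0.0, 3.0, 1.0])
    return ids, observed, predicted, sim


@pytest.fixture
def simple_table():
    rng = np.random.default_rng(11)
    n = 12
    observed = rng.normal(size=n)
    return ActivityTable(
        [f"c{i}" for i in range(n)],
        observed,
        {"good": observed + 0.1 * rng.normal(size=n), "noise": rng.normal(size=n)},
    )


def random_similarity(n, rng):
    """A valid random similarity matrix with all off-diagonal sims < 1."""
    v = rng.uniform(0.0, 0.95, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix([f"c{i}" for i in range(n)], v)
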