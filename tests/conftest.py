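import numpy as np
import pytest

from funcscreen.synthdata import WorldSpec, generate_world

# 50 drug-like molecules for round-trip / invariance fixtures
DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # caffeine
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",                 # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",               # naproxen
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",             # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",                # propranolol
    "CN(C)C(=N)NC(N)=N",                          # metformin
    "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O",          # diazepam
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",      # warfarin
    "Clc1ccccc1-c1nc2ccccc2[nH]1",
    "NC(=O)c1ccc(N)cc1",
    "OCC(O)C(O)C(O)C(O)CO",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",              # salbutamol
    "COc1cc2c(cc1OC)CCN(C)CC2",
    "CN1CCC(CC1)=C1c2ccccc2CCc2ccccc21",
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",         # hydrochlorothiazide
    "CC1=CC(=O)C=CC1=O",
    "Oc1ccc(cc1)C(c1ccc(O)cc1)C1CCCCC1",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                 # procainamide
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",              # imipramine
    "NC(Cc1ccc(O)cc1)C(=O)O",                     # tyrosine
    "CC(N)Cc1ccccc1",                             # amphetamine
    "OC(=O)c1ccccc1O",                            # salicylic acid
    "CCOC(=O)c1ccccc1N",
    "Nc1ncnc2[nH]cnc12",                          # adenine
    "O=c1[nH]cnc2[nH]ncc12",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",              # melatonin
    "NCCc1c[nH]c2ccccc12",                        # tryptamine
    "OC(=O)CCc1ccccc1",
    "COc1ccccc1OCCNCC(O)COc1cccc2[nH]c3ccccc3c12",
    "CC(C)C(N)C(=O)O",                            # valine
    "CSCCC(N)C(=O)O",                             # methionine
    "OCc1ccccc1",
    "Clc1ccc(cc1)C(=O)c1ccc(Cl)cc1",
    "CC(C)(C)c1ccc(O)cc1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "CN1CCN(CC1)c1ccc(N)cc1",
    "Fc1ccc(cc1)C(=O)CCCN1CCC(O)(CC1)c1ccc(Cl)cc1",  # haloperidol
    "CCOc1ccc2nc(S(N)(=O)=O)sc2c1",               # ethoxzolamide
    "Cc1ccc(cc1)S(=O)(=O)N",
    "O=C1CCCN1",
    "c1ccc2c(c1)ccc1ccccc21",                     # phenanthrene
    "OC(=O)C1CCCCC1",
    "NCCCC(N)C(=O)O",
    "COC(=O)c1ccccc1O",
    "CC1CCC(CC1)NC",
    "O=C(O)c1cc(O)c(O)c(O)c1",                    # gallic acid
    "N#Cc1ccccc1",
    "CC(=O)c1ccc2ccccc2c1",
]


@pytest.fixture(scope="session")
def drug_smiles():
    return list(DRUG_SMILES)


@pytest.fixture(scope="session")
def small_world():
    """Desk-scale planted world shared by read-only tests."""
    return generate_world(WorldSpec(n_proteins=12, n_molecules=60,
                                    records_per_protein=30, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
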