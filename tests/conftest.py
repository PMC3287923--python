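import numpy as np
import pytest

from famlod.pedigree import Individual, Pedigree


def make_trio(fid="T"):
    return Pedigree(
        fid,
        [
            Individual(iid="dad", fid=fid, father=None, mother=None, sex=1),
            Individual(iid="mom", fid=fid, father=None, mother=None, sex=2),
            Individual(iid="kid", fid=fid, father="dad", mother="mom", sex=1),
        ],
    )


def make_sib_quartet(fid="S"):
    members = [
        Individual(iid="dad", fid=fid, father=None, mother=None, sex=1),
        Individual(iid="mom", fid=fid, father=None, mother=None, sex=2),
        Individual(iid="sib1", fid=fid, father="dad", mother="mom", sex=1),
        Individual(iid="sib2", fid=fid, father="dad", mother="mom", sex=2),
    ]
    return Pedigree(fid, members)


def make_cousin_mating(fid="C"):
    """Three generations ending in a first-cousin mating and an inbred child."""
    mk = lambda iid, pat, mat, sex: Individual(iid=iid, fid=fid, father=pat, mother=mat, sex=sex)
    members = [
        mk("gpa", None, None, 1),
        mk("gma", None, None, 2),
        mk("unc", "gpa", "gma", 1),
        mk("aun", "gpa", "gma", 2),
        mk("wife", None, None, 2),
        mk("husb", None, None, 1),
        mk("cu1", "unc", "wife", 1),  # cousins cu1 x cu2 mate
        mk("cu2", "husb", "aun", 2),
        mk("inb", "cu1", "cu2", 1),
    ]
    return Pedigree(fid, members)


@pytest.fixture(scope="session")
def trio():
    return make_trio()


@pytest.fixture(scope="session")
def sib_quartet():
    return make_sib_quartet()


@pytest.fixture(scope="session")
def cousin_ped():
    return make_cousin_mating()


def mc_gene_drop_kinship(ped, n_drops, seed):
    """Monte-Carlo kinship oracle: vectorized gene dropping of labeled
    founder alleles, independent of the tabular recursion under test.

    Phi_ij is estimated as the mean fraction of the four (allele of i,
    allele of j) pairs that are identical by descent. Returns (phi_hat, se).
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    alleles = {}
    next_label = 0
    for ind in ped.members:
        if ind.is_founder:
            a = np.full(n_drops, next_label)
            b = np.full(n_drops, next_label + 1)
            next_label += 2
        else:
            fa, fb = alleles[ind.father]
            ma, mb = alleles[ind.mother]
            pick = rng.integers(0, 2, size=n_drops, dtype=np.int8)
            a = np.where(pick == 0, fa, fb)
            pick = rng.integers(0, 2, size=n_drops, dtype=np.int8)
            b = np.where(pick == 0, ma, mb)
        alleles[ind.iid] = (a, b)
    phi = np.zeros((n, n))
    se = np.zeros((n, n))
    ids = ped.ids
    for i in range(n):
        ai, bi = alleles[ids[i]]
        for j in range(i, n):
            aj, bj = alleles[ids[j]]
            share = ((ai == aj).astype(np.float64) + (ai == bj) + (bi == aj) + (bi == bj)) / 4.0
            phi[i, j] = phi[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_drops)
    return phi, se
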