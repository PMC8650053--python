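"""Shared fixtures and independent oracle helpers.

The helpers here (gene-dropping kinship, random pedigree generation) are
deliberately written from first principles, independent of the package code
paths they are used to check.
"""

import numpy as np
import pandas as pd
import pytest

from treeresp import animal_model, orchard_sim, pedigree


# ---------------------------------------------------------------------------
# oracle helpers


def random_pedigree(rng: np.random.Generator, n_founders=10, gens=(20, 20)):
    """Random multi-generation pedigree; parents drawn from the previous layer."""
    records = [(f"F{i}", None, None) for i in range(n_founders)]
    prev = [r[0] for r in records]
    for g, size in enumerate(gens):
        layer = []
        for k in range(size):
            s, d = rng.choice(len(prev), size=2, replace=False)
            ind = f"G{g}_{k}"
            records.append((ind, prev[s], prev[d]))
            layer.append(ind)
        prev = layer
    return pedigree.validate_pedigree(records)


def gene_drop_relationships(ped, n_rep: int, rng: np.random.Generator):
    """Monte-Carlo numerator relationships by gene dropping.

    Each founder (and each unknown-parent slot) carries unique allele labels;
    offspring inherit one random allele per parent and replicate.  Returns
    ``(A_hat, A_se)`` where ``A = 2 * kinship`` and kinship(i, j) is the
    probability that one allele drawn from each of i and j is IBD.
    """
    n = len(ped)
    idx = {ind: i for i, ind in enumerate(ped.ids)}
    alleles = np.empty((n, 2, n_rep), dtype=np.int32)
    label = 0
    for i, (ind, sire, dam) in enumerate(ped.records):
        for slot, parent in enumerate((sire, dam)):
            if parent is None:
                alleles[i, slot, :] = label
                label += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                alleles[i, slot, :] = alleles[idx[parent], pick, np.arange(n_rep)]
    A_hat = np.zeros((n, n))
    A_se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            per_rep = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    per_rep += alleles[i, a] == alleles[j, b]
            per_rep *= 0.5  # 2 * kinship = (1/4 sum of matches) * 2
            A_hat[i, j] = A_hat[j, i] = per_rep.mean()
            A_se[i, j] = A_se[j, i] = per_rep.std(ddof=1) / np.sqrt(n_rep)
    return A_hat, A_se


def dense_reml_loglik(y, X, V):
    """Direct restricted log-likelihood (basis-invariant form), for oracles."""
    m, p = X.shape
    sign, logdetV = np.linalg.slogdet(V)
    assert sign > 0
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign, logdetC = np.linalg.slogdet(XtViX)
    assert sign > 0
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ b
    quad = float(resid @ Vi @ y)
    return -0.5 * (
        logdetV + logdetC - logdet_xtx + quad + (m - p) * np.log(2 * np.pi)
    )


def add_mai(phen: pd.DataFrame) -> pd.DataFrame:
    out = phen.copy()
    out["mai"] = out["height"] / out["age"]
    return out


@pytest.fixture(scope="session")
def oracle():
    """Namespace fixture exposing the oracle helpers."""

    class NS:
        pass

    ns = NS()
    ns.random_pedigree = random_pedigree
    ns.gene_drop_relationships = gene_drop_relationships
    ns.dense_reml_loglik = dense_reml_loglik
    ns.add_mai = add_mai
    return ns


# ---------------------------------------------------------------------------
# datasets


SMALL_CFG = dict(n_parents=15, n_sites=8, offspring_per_site=25, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    return orchard_sim.SimConfig(**SMALL_CFG)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return orchard_sim.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_A(small_dataset):
    return pedigree.numerator_relationship_matrix(small_dataset.pedigree)


@pytest.fixture(scope="session")
def small_fit(small_dataset, small_A):
    phen = add_mai(small_dataset.phenotypes)
    return animal_model.fit_animal_model(
        phen, small_dataset.pedigree, small_A, traits=("mai", "density")
    )
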