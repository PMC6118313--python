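import numpy as np
import pytest

import medlmm


@pytest.fixture(scope="session")
def small_panel():
    """Structured panel (120 lines, 200 SNPs, 2 populations) with kinship."""
    g = medlmm.simulate_genotypes(120, 200, n_pops=2, divergence=0.3, seed=7)
    k = medlmm.ibs_kinship(g)
    return g, k


@pytest.fixture(scope="session")
def mediation_data(small_panel):
    """One mediation dataset with known truth on the structured panel."""
    g, k = small_panel
    m, y, truth = medlmm.simulate_mediation(g, rho_gamma=0.0, seed=7)
    x = g.calls[:, truth.causal_snp_index]
    return g, k, x, m, y, truth


@pytest.fixture(scope="session")
def tiny_tsv(tmp_path_factory):
    """Hand-written 2-line, 3-SNP genotype TSV fixture."""
    path = tmp_path_factory.mktemp("fixtures") / "tiny.tsv"
    path.write_text(
        "line\tchr1:100\tchr1:200\tchr2:50\n"
        "lineA\t0\t1\t0\n"
        "lineB\t1\t1\t0\n"
    )
    return path


def rng_psd_kinship(n: int, seed: int) -> np.ndarray:
    """Random PSD correlation-like matrix with unit diagonal."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n + 5))
    k = a @ a.T
    d = np.sqrt(np.diag(k))
    return k / np.outer(d, d)
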