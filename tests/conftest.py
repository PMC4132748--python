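import numpy as np
import pytest

from macrorate.lineages import read_groups_tsv
from macrorate.mrca_age import Marker, MarkerMap
from macrorate.pipeline import GROUPS_FIXTURE, packaged_path
from macrorate.rate_mle import fit_mle
from macrorate.lineages import aggregate_generation_counts


@pytest.fixture(scope="session")
def paper_groups():
    """Packaged founder-group table (five BRCA1 mutations, 13 families)."""
    return read_groups_tsv(packaged_path(GROUPS_FIXTURE))


@pytest.fixture(scope="session")
def paper_counts(paper_groups):
    return aggregate_generation_counts(paper_groups)


@pytest.fixture(scope="session")
def paper_mu_hat(paper_counts):
    return fit_mle(paper_counts)


def build_toy_map(n_markers: int = 17, span_bp: int = 3_200_000, seed: int = 7):
    """A biallelic SNP map spanning ``span_bp`` centred on a disease locus,
    with ancestral-allele frequencies drawn uniformly in [0.2, 0.8]."""
    rng = np.random.default_rng(seed)
    disease_bp = 41_250_000
    offsets = np.linspace(-span_bp // 2, span_bp // 2, n_markers).astype(int)
    markers = []
    for k, off in enumerate(offsets):
        bp = disease_bp + int(off) if off != 0 else disease_bp + 1000
        p = float(rng.uniform(0.2, 0.8))
        markers.append(
            Marker(
                marker_id=f"rs{k}",
                position_bp=bp,
                position_cm=bp / 1e6,
                ancestral="A",
                frequencies={"A": p, "G": 1 - p},
            )
        )
    return MarkerMap(markers=tuple(markers), disease_cm=disease_bp / 1e6)


@pytest.fixture(scope="session")
def toy_map():
    return build_toy_map()
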