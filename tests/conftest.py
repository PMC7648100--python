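import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ibdmr import summary_io as sio
from ibdmr import synthetic_data as sd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def frame_to_assocs(df):
    """Convert a summary-statistic DataFrame into SnpAssociation records."""
    out = []
    for row in df.itertuples(index=False):
        eaf = None if (row.eaf is None or (isinstance(row.eaf, float) and math.isnan(row.eaf))) else float(row.eaf)
        out.append(
            sio.SnpAssociation(
                rsid=row.rsid,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=eaf,
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
            )
        )
    return out


def simulated_instrument(cfg: sd.SimConfig) -> sio.HarmonizedInstrument:
    """Simulate a pair and align it without the allele-matching round trip.

    Uses the truth record's swap flags directly, so tests of estimators are
    not coupled to the harmonization code path (which has its own tests).
    """
    exposure, outcome, truth = sd.simulate_pair(cfg)
    swap = truth.table["outcome_swapped"].to_numpy()
    y = outcome["beta"].to_numpy() * np.where(swap, -1.0, 1.0)
    return sio.HarmonizedInstrument(
        rsids=tuple(exposure["rsid"]),
        x=exposure["beta"].to_numpy(),
        sx=exposure["se"].to_numpy(),
        y=y,
        sy=outcome["se"].to_numpy(),
    )


def random_instrument(rng: np.random.Generator, n_snp: int = 8) -> sio.HarmonizedInstrument:
    """A generic well-conditioned instrument for algebraic oracle checks."""
    x = rng.uniform(0.05, 0.3, n_snp) * rng.choice([-1.0, 1.0], n_snp)
    return sio.HarmonizedInstrument(
        rsids=tuple(f"rs{i}" for i in range(n_snp)),
        x=x,
        sx=rng.uniform(0.005, 0.02, n_snp),
        y=0.4 * x + rng.normal(0, 0.02, n_snp),
        sy=rng.uniform(0.01, 0.05, n_snp),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_instrument():
    """Deterministic 5-SNP instrument with mild heterogeneity."""
    return random_instrument(np.random.default_rng(7), n_snp=5)
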