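import numpy as np
import pytest

from bwmr.instruments import InstrumentSet
from bwmr.summary_data import HarmonisedInstrument, SummaryAssociation


def make_instruments(bx, by, sy, sx=None, ids=None) -> list[HarmonisedInstrument]:
    """Build harmonised instruments from plain arrays (test helper)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    ids = ids or [f"rs{i + 1}" for i in range(len(bx))]
    return [
        HarmonisedInstrument(
            snp_id=i, beta_exposure=x, se_exposure=ex, beta_outcome=y, se_outcome=ey
        )
        for i, x, ex, y, ey in zip(ids, bx, sx, by, sy)
    ]


def records_from_frame(df, binary=False) -> list[SummaryAssociation]:
    """Turn a generator DataFrame into SummaryAssociation records."""
    out = []
    for r in df.to_dict("records"):
        out.append(
            SummaryAssociation(
                snp_id=r["snp"],
                effect_allele=r["effect_allele"],
                other_allele=r["other_allele"],
                beta=r["beta"],
                se=r["se"],
                pvalue=r["pvalue"],
                eaf=r.get("eaf"),
                n=r.get("n"),
                n_cases=r.get("n_cases"),
                n_controls=r.get("n_controls"),
            )
        )
    return out


# A small heterogeneous table used across estimator and diagnostic tests.
FIVE_BX = np.array([0.10, 0.08, 0.12, 0.05, 0.09])
FIVE_SX = np.array([0.01, 0.01, 0.01, 0.01, 0.01])
FIVE_BY = np.array([0.05, 0.03, 0.07, 0.01, 0.04])
FIVE_SY = np.array([0.010, 0.015, 0.012, 0.020, 0.011])


@pytest.fixture
def five_snp_instruments():
    return make_instruments(FIVE_BX, FIVE_BY, FIVE_SY, FIVE_SX)


@pytest.fixture
def five_snp_set(five_snp_instruments):
    return InstrumentSet("five", five_snp_instruments)
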