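import numpy as np
import pandas as pd
import pytest

from mirnet.qpcr import CtTable


def make_ct(values: dict[str, list[float]], groups: dict[str, str],
            reference: str = "REF") -> CtTable:
    """Small hand-built CtTable; values maps feature -> per-sample Ct."""
    df = pd.DataFrame.from_dict(values, orient="index",
                                columns=list(groups))
    return CtTable(values=df.astype(float), groups=groups,
                   reference=reference)


@pytest.fixture
def two_group_ct() -> CtTable:
    """Two features, two groups of two samples, noise-free.

    miR-A sits 2 cycles lower in the cisplatin group (fourfold up);
    miR-B is flat.
    """
    groups = {"sal_1": "saline", "sal_2": "saline",
              "cis_1": "cisplatin", "cis_2": "cisplatin"}
    return make_ct(
        {"miR-A": [28.0, 28.0, 26.0, 26.0],
         "miR-B": [30.0, 30.0, 30.0, 30.0],
         "REF": [20.0, 20.0, 20.0, 20.0]},
        groups,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
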