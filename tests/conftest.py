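import pytest

from asbestos_risk import ExposureParameters, PotencyFactors
from asbestos_risk.synthetic import (
    tehran_annual_means,
    tehran_lung_table,
    tehran_mesothelioma_table,
    tehran_observed_c_avg,
)


@pytest.fixture(scope="session")
def tehran_series():
    return tehran_annual_means()


@pytest.fixture(scope="session")
def lung_ref():
    """Published lung-cancer risk columns, indexed by year."""
    return tehran_lung_table()


@pytest.fixture(scope="session")
def meso_ref():
    """Published mesothelioma risk columns, indexed by year."""
    return tehran_mesothelioma_table()


@pytest.fixture(scope="session")
def observed_c_avg():
    return tehran_observed_c_avg()


@pytest.fixture(scope="session")
def default_params():
    return ExposureParameters()


@pytest.fixture(scope="session")
def default_potency():
    return PotencyFactors()


def write_csv(path, rows, header="year,region,concentration,n_samples"):
    """Write a small monitoring CSV from (year, region, conc, n) tuples."""
    lines = [header]
    for row in rows:
        lines.append(",".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
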