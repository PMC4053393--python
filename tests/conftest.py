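import numpy as np
import pytest

import antnet as an


@pytest.fixture
def triangle5():
    """5x5 perfectly nested matrix: row i has 1s in columns 0..4-i."""
    return np.array([[1] * (5 - i) + [0] * i for i in range(5)])


@pytest.fixture
def degree_network():
    """Network whose ant degrees are [5, 3, 1, 1, 1, 1] over 5 plants."""
    records = []
    degrees = [5, 3, 1, 1, 1, 1]
    for i, d in enumerate(degrees):
        for j in range(d):
            records.append(an.InteractionRecord(f"p{j + 1}", f"a{i + 1}", "diurnal", 1))
    return an.build_network(records, "diurnal")


@pytest.fixture
def records_csv(tmp_path):
    """Write a records CSV and return its path; content given per-test."""

    def _write(rows, header="plant_id,ant_species,period,count"):
        path = tmp_path / "records.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def small_community():
    """A compact synthetic community (fast enough for pipeline tests)."""
    config = an.SyntheticConfig(n_plants=12, n_ants=8, seed=11)
    return an.generate_community(config)


@pytest.fixture
def community_files(tmp_path, small_community):
    records, attributes, _ = small_community
    rp = tmp_path / "records.csv"
    ap = tmp_path / "attributes.csv"
    with open(rp, "w") as fh:
        fh.write("plant_id,ant_species,period,count\n")
        for r in records:
            fh.write(f"{r.plant_id},{r.ant_species},{r.period},{r.count}\n")
    with open(ap, "w") as fh:
        fh.write("plant_id,height_m,efn_total\n")
        for a in attributes:
            fh.write(f"{a.plant_id},{a.height_m:.6f},{a.efn_total:.6f}\n")
    return rp, ap
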