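import numpy as np
import pandas as pd
import pytest

from floodcontam.io import SurveyTable, validate


def make_survey(units_rows, catches_rows, registry_rows):
    """Assemble a SurveyTable from plain tuples (order: canonical columns)."""
    units = pd.DataFrame(
        units_rows,
        columns=["unit_id", "locality", "habitat", "gear", "campaign_date", "area_m2"],
    )
    units["campaign_date"] = pd.to_datetime(units["campaign_date"]).dt.date
    units["area_m2"] = units["area_m2"].astype(float)
    units["season"] = "Q" + pd.to_datetime(units["campaign_date"]).dt.quarter.astype(str)
    catches = pd.DataFrame(
        catches_rows,
        columns=["unit_id", "species_id", "n_individuals", "total_weight_g"],
    )
    if len(catches):
        catches["n_individuals"] = catches["n_individuals"].astype(int)
        catches["total_weight_g"] = catches["total_weight_g"].astype(float)
    registry = pd.DataFrame(
        registry_rows, columns=["species_id", "species_name", "origin"]
    )
    survey = SurveyTable(units=units, catches=catches, registry=registry)
    survey.report = validate(survey)
    return survey


@pytest.fixture
def small_registry_rows():
    return [
        ("nat1", "Nativops one", "native"),
        ("nat2", "Nativops two", "native"),
        ("nnv1", "Xenopisces one", "non_native"),
        ("unc1", "Ambiguops one", "unclassified"),
    ]


@pytest.fixture
def small_survey(small_registry_rows):
    """Two clean sampling units: one gillnet on a lake, one on a river."""
    return make_survey(
        [
            ("u1", "lgar", "lake", "gillnet", "2005-05-15", 368.0),
            ("u2", "rbai", "river", "gillnet", "2005-05-15", 368.0),
        ],
        [
            ("u1", "nat1", 4, 200.0),
            ("u1", "nat2", 2, 100.0),
            ("u1", "nnv1", 1, 68.0),
            ("u2", "nat1", 3, 120.0),
        ],
        small_registry_rows,
    )


def random_valid_survey(seed, n_units=6, n_species=5):
    """Randomized but structurally valid survey for round-trip properties."""
    rng = np.random.default_rng(seed)
    localities = ["lgar", "lgua", "rbai", "rivi", "lfec"]
    origins = ["native", "non_native", "unclassified"]
    registry = [
        (f"sp{i}", f"Species {i}", origins[rng.integers(0, 3)]) for i in range(n_species)
    ]
    units, catches = [], []
    for u in range(n_units):
        loc = localities[rng.integers(0, len(localities))]
        habitat = "lake" if loc.startswith("l") else "river"
        gear = "seine" if (habitat == "lake" and rng.random() < 0.4) else "gillnet"
        date = f"20{rng.integers(0, 18):02d}-{rng.integers(1, 13):02d}-15"
        area = float(np.round(rng.uniform(30.5, 368.0), 2))
        uid = f"u{u}"
        units.append((uid, loc, habitat, gear, date, area))
        for s in range(n_species):
            if rng.random() < 0.6:
                n = int(rng.integers(1, 40))
                w = float(np.round(n * rng.uniform(5, 300), 3))
                catches.append((uid, f"sp{s}", n, w))
    return make_survey(units, catches, registry)
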