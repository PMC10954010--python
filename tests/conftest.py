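import pandas as pd
import pytest

from foodsec import (
    classify_dataset,
    complete_cases,
    compute_indicators,
    default_config,
    default_params,
    generate,
)
from foodsec.survey import SurveyDataset, coping_column, day_column, required_columns
from foodsec.synthetic import params_from_dict, params_to_dict


@pytest.fixture(scope="session")
def config():
    return default_config()


def make_row(
    config,
    id="h1",
    days=0,
    food_spend=300.0,
    total_spend=1000.0,
    coping_yes=(),
    area="urban",
    head_sex="female",
    head_age=48.0,
    civil_status="single",
    hh_size=4,
):
    """One raw survey row; ``days`` is a scalar for all groups or a dict."""
    if not isinstance(days, dict):
        days = {g: days for g in config.group_names}
    row = {
        "id": id,
        "area": area,
        "head_sex": head_sex,
        "head_age": head_age,
        "civil_status": civil_status,
        "hh_size": hh_size,
        "food_spend": food_spend,
        "total_spend": total_spend,
    }
    for g in config.group_names:
        row[day_column(g)] = days.get(g, 0)
    for item in config.item_names:
        row[coping_column(item)] = 1 if item in coping_yes else 0
    return row


def make_dataset(config, rows):
    df = pd.DataFrame(rows, columns=list(required_columns(config)))
    return SurveyDataset(df=df, config=config)


@pytest.fixture
def row_factory(config):
    return lambda **kw: make_row(config, **kw)


@pytest.fixture
def dataset_factory(config):
    return lambda rows: make_dataset(config, rows)


@pytest.fixture(scope="session")
def calibrated_scored():
    """n=5000 calibrated synthetic survey, scored and complete-cased."""
    params = params_from_dict({**params_to_dict(default_params()), "n": 5000})
    ds = generate(params, seed=1)
    scored = classify_dataset(compute_indicators(ds))
    comp = complete_cases(scored)
    comp.meta["intended"] = ds.meta["intended"].loc[comp.df.index]
    return comp
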