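import numpy as np
import pandas as pd
import pytest

from scalorank import IndicatorMatrix, IndicatorSpec


@pytest.fixture
def small_schema():
    return [
        IndicatorSpec("beds", cluster="institutional"),
        IndicatorSpec("clinics", cluster="institutional"),
        IndicatorSpec("doctors", cluster="human_resource"),
        IndicatorSpec("health_houses", cluster="rural_institutional"),
    ]


@pytest.fixture
def small_matrix(small_schema):
    values = pd.DataFrame(
        {
            "beds": [0.0, 1.0, 2.0, 3.0],
            "clinics": [3.0, 2.0, 1.0, 0.0],
            "doctors": [0.5, 0.5, 0.5, 0.5],
            "health_houses": [0.0, 0.3, 0.6, 0.9],
        },
        index=["North", "East", "South", "West"],
    )
    return IndicatorMatrix(values=values, schema=small_schema)


def square(x, y):
    return {
        "type": "Polygon",
        "coordinates": [[[x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]],
    }


@pytest.fixture
def grid_geojson():
    """Synthetic 2x2 polygon grid keyed by region name."""
    names = ["North", "East", "South", "West"]
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": n},
                "geometry": square(i % 2, i // 2),
            }
            for i, n in enumerate(names)
        ],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
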