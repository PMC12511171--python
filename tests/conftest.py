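import io as _io
import json

import numpy as np
import pandas as pd
import pytest
import shapely.geometry

from gliospatial.io import SlideCellMap, read_cell_table, read_region_annotations
from gliospatial.regions import Region, RegionSet
from gliospatial.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def tiny_cell_csv():
    return _io.StringIO(
        "cell_id,x_um,y_um,cell_class\n"
        "c1,10.5,20.0,TUMOR\n"
        "c2,30.0,40.0,IBA1\n"
        "c3,50.25,60.0,CD8\n"
    )


def square(x0, y0, side):
    return shapely.geometry.box(x0, y0, x0 + side, y0 + side)


@pytest.fixture
def three_squares_geojson(tmp_path):
    """Three side-by-side 1000 μm squares labeled CORE/TRANSITION/PERIPHERY."""
    features = [
        {
            "type": "Feature",
            "properties": {"region_label": label},
            "geometry": shapely.geometry.mapping(square(1000 * i, 0, 1000)),
        }
        for i, label in enumerate(["CORE", "TRANSITION", "PERIPHERY"])
    ]
    path = tmp_path / "regions.geojson"
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


@pytest.fixture
def square_region_set():
    """Same layout as three_squares_geojson, constructed directly."""
    regions = {
        label: Region(label=label, geometry=square(1000 * i, 0, 1000))
        for i, label in enumerate(["CORE", "TRANSITION", "PERIPHERY"])
    }
    return RegionSet(patient_id="p1", regions=regions)


def cell_map_from(points, patient_id="p1"):
    """Build a SlideCellMap from (x, y, cell_class) triples."""
    df = pd.DataFrame(points, columns=["x", "y", "cell_class"])
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    return SlideCellMap(patient_id=patient_id, cells=df)


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale synthetic cohort shared by read-only tests."""
    config = SyntheticCohortConfig(
        n_patients=8, region_areas=(0.5, 0.5, 0.5), missing_region_prob=0.0, seed=11
    )
    return config, generate_cohort(config)
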