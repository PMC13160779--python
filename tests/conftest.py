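import numpy as np
import pytest

from gtwrkit import synth


@pytest.fixture(scope="session")
def regions13():
    return synth.generate_region_lattice(13, seed=1)


@pytest.fixture(scope="session")
def years():
    return [2020, 2021, 2022]


@pytest.fixture(scope="session")
def panel13(regions13, years):
    panel = synth.generate_covariate_panel(regions13, years, seed=7)
    specs = synth.default_surface_specs()
    surfaces = synth.generate_coefficient_surfaces(regions13, years, specs)
    panel = panel.copy()
    panel["y"] = synth.generate_outcome(panel, surfaces, noise_sd=0.25, seed=11)
    return panel


@pytest.fixture(scope="session")
def design13(panel13):
    covs = [c for c in panel13.columns if c.startswith("x")]
    X = np.column_stack([np.ones(len(panel13)), panel13[covs].to_numpy()])
    return (
        X,
        panel13["y"].to_numpy(),
        panel13[["u", "v"]].to_numpy(),
        panel13["year"].to_numpy(),
        ("const", *covs),
    )


def grid_regions(nx, ny):
    """Unit-square lattice of RegionGeometry cells, row-major ids."""
    from shapely.geometry import box

    out = []
    for j in range(ny):
        for i in range(nx):
            poly = box(i, j, i + 1, j + 1)
            out.append(
                synth.RegionGeometry(
                    region_id=f"G{j * nx + i:02d}",
                    polygon=poly,
                    centroid=(i + 0.5, j + 0.5),
                )
            )
    return out
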