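import numpy as np
import pytest

from vineweed import GeoTransform, Scene
from vineweed.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """12 x 12 m RGB vineyard at 2 cm pixels, 15% weed coverage."""
    spec = SceneSpec(field_size=(12.0, 12.0), pixel_size=0.02, seed=1)
    scene, labels = generate_scene(spec)
    return scene, labels, spec


@pytest.fixture(scope="session")
def small_scene_rgnir():
    spec = SceneSpec(field_size=(12.0, 12.0), pixel_size=0.02, camera="RGNIR", seed=2)
    scene, labels = generate_scene(spec)
    return scene, labels, spec


def flat_scene(nrow=100, ncol=100, pixel_size=0.02, dsm=None, value=0.3,
               camera="RGB", nodata_mask=None):
    """Minimal hand-built Scene with constant bands unless overridden."""
    bands = {b: np.full((nrow, ncol), value) for b in
             (("R", "G", "B") if camera == "RGB" else ("R", "G", "NIR"))}
    if dsm is None:
        dsm = np.full((nrow, ncol), 100.0)
    t = GeoTransform.north_up(0.0, nrow * pixel_size, pixel_size)
    return Scene(bands=bands, dsm=dsm, transform=t, crs="EPSG:32630",
                 camera=camera, nodata_mask=nodata_mask)
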