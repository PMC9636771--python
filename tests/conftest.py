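import numpy as np
import pytest

from mibipipe import ChannelStack, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(
        raster_px=256, field_width_um=100.0,
        n_cells_per_class={"neuron": 10, "microglia": 6, "astrocyte": 5,
                           "endothelial": 3},
        n_objects_per_class={"plaque": 5, "tangle": 8},
        slide_border_px=16, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


def make_stack(arrays: dict, pixel_size_um: float = 1.0,
               fov_id: str = "fov0") -> ChannelStack:
    names = list(arrays)
    pixels = np.stack([np.asarray(arrays[n], dtype=float) for n in names])
    return ChannelStack(pixels, names, pixel_size_um=pixel_size_um,
                        fov_id=fov_id)
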