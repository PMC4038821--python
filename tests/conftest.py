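"""Shared fixtures: seeded RNGs and small rendered fields."""

import numpy as np
import pytest

from prolifmark.synthetic_imaging import (
    NucleusRecord,
    RenderConfig,
    StainVectors,
    place_nuclei,
    render_field,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def vectors():
    return StainVectors()


@pytest.fixture(scope="session")
def small_render_config():
    """A quarter-scale field with generous spacing: well-separated nuclei."""
    return RenderConfig(width=640, height=480, noise_sd=2.0, min_spacing_factor=2.2)


def make_field(n_pos, n_neg, config, vectors, seed, stain_mode="MIB1",
               dna_content=1.5, extra_geoms=(), extra_pos=True):
    """Render a field with n_pos marker-positive and n_neg negative nuclei.

    ``extra_geoms`` are appended verbatim (e.g. hand-placed touching pairs);
    they are marker-positive when ``extra_pos``.
    """
    rng = np.random.default_rng(seed)
    geoms = list(place_nuclei(n_pos + n_neg, config, rng)) + list(extra_geoms)
    records = []
    for i, g in enumerate(geoms):
        pos = i < n_pos or (i >= n_pos + n_neg and extra_pos)
        records.append(NucleusRecord(
            label=i + 1, geometry=g, mib1_pos=pos, phh3_pos=pos,
            mitotically_visible=False, dna_content=dna_content, phase="S"))
    field = render_field(records, stain_mode, vectors, config, rng,
                         frame=(config.height, config.width))
    return field


@pytest.fixture(scope="session")
def mib1_field_50(small_render_config, vectors):
    """50 well-separated DAB-positive nuclei."""
    return make_field(50, 0, small_render_config, vectors, seed=7)
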