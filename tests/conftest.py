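"""Shared fixtures: phantoms and segmentations are expensive, so they are
generated once per session and treated as read-only by tests."""

import pytest

from axskel.core import center_of_mass, round_half_away
from axskel.morph import segment_morph
from axskel.phantom import (
    LesionSpec,
    PetPhantomSpec,
    PhantomSpec,
    generate_phantom_ldct,
    generate_phantom_pet,
)
from axskel.voi import build_voi_inventory


@pytest.fixture(scope="session")
def phantom():
    """Default noise-free phantom scan: (ct, labels)."""
    return generate_phantom_ldct(PhantomSpec(seed=7, ct_noise_sd_hu=0.0))


@pytest.fixture(scope="session")
def phantom_labels(phantom):
    return phantom[1]


@pytest.fixture(scope="session")
def morph_seg(phantom_labels):
    return segment_morph(phantom_labels)


@pytest.fixture(scope="session")
def morph_vois(morph_seg):
    vois, qc = build_voi_inventory(morph_seg)
    return vois


@pytest.fixture(scope="session")
def lesion_setup(phantom_labels, morph_seg, morph_vois):
    """Zero-noise PET with five planted lesions across VOI families.

    Returns (pet, truth, vois); the truth object records the lesion
    centers that define per-VOI positivity.
    """
    seg = morph_seg

    def com_vox(mask):
        return tuple(round_half_away(center_of_mass(mask)))

    lesions = [
        LesionSpec(peak_suv=24.0, sigma_mm=2.0, center_vox=com_vox(seg.ivd["T7-T8"])),
        LesionSpec(peak_suv=28.0, sigma_mm=2.0, center_vox=seg.find_center("FJ", "L2-L3", "left").ijk),
        LesionSpec(peak_suv=24.0, sigma_mm=2.0, center_vox=seg.find_center("CVJ", "T4", "right").ijk),
        LesionSpec(peak_suv=28.0, sigma_mm=2.0, center_vox=com_vox(seg.sij["left"])),
        LesionSpec(peak_suv=28.0, sigma_mm=2.0, center_vox=com_vox(seg.ivd["L3-L4"])),
    ]
    pet, truth = generate_phantom_pet(
        phantom_labels, PetPhantomSpec(lesions=lesions, noise_sd=0.0, seed=11)
    )
    return pet, truth, morph_vois


@pytest.fixture(scope="session")
def atlas_library():
    """Five-scan partial-atlas library over a range of anatomical scales;
    also returns the per-scan (ct, labels, morph seg) triples."""
    from axskel.atlas import make_partial_atlases

    library, scans = [], []
    for i, s in enumerate([0.92, 0.96, 1.0, 1.04, 1.08]):
        ct, labels = generate_phantom_ldct(PhantomSpec(seed=20 + i, scale=s))
        seg = segment_morph(labels)
        atlases, _ = make_partial_atlases(ct, labels, seg)
        library.append(atlases)
        scans.append((ct, labels, seg))
    return library, scans


@pytest.fixture(scope="session")
def atlas_seg(atlas_library):
    """Atlas segmentation of the middle library scan (self-atlas run)."""
    from axskel.atlas import segment_atlas

    library, scans = atlas_library
    ct, labels, morph_ref = scans[2]
    out = segment_atlas(ct, labels, library)
    return out, morph_ref
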