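"""Shared fixtures: small phantom cohorts and narrow network specs.

Everything is generated programmatically at fixture time; session scoping
keeps the larger cohorts to a single build per run.
"""

import pytest

from sucgan import (DiscriminatorSpec, GeneratorSpec, PhantomConfig,
                    generate_cohort, generate_subject)


@pytest.fixture(scope="session")
def noise_free_config():
    """3-subject, 64x64, noise-free phantom configuration."""
    return PhantomConfig(n_subjects=3, grid=(64, 64), slice_count_choices=(8,),
                         noise_sd={"MR": 0.0, "CT": 0.0}, seed=7)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return generate_cohort(noise_free_config)


@pytest.fixture(scope="session")
def noisy_case():
    cfg = PhantomConfig(n_subjects=2, grid=(64, 64), slice_count_choices=(8,),
                        noise_sd={"MR": 8.0, "CT": 15.0}, seed=11)
    return generate_subject(cfg, "N01", 8)


@pytest.fixture(scope="session")
def study_shaped_cohort():
    """Cohort shaped like the emulated clinical study: 11 subjects on a
    144x144 grid, 50 slices for subjects 1, 2, 3, 5 and 44 for the rest."""
    cfg = PhantomConfig(seed=3)
    return generate_cohort(cfg)


@pytest.fixture()
def narrow_gen_spec():
    """Small depth-2 generator for fast training tests."""
    return GeneratorSpec(depth=2, stage_features=(8, 16, 32), dropout_rate=0.0)


@pytest.fixture()
def narrow_disc_spec():
    return DiscriminatorSpec(block_features=(8, 16, 32), kernel_size=3)
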