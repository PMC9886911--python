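"""Simulated BMT cohorts: syngeneic and allogeneic recipients, with and
without MSC treatment, imaged at fixed times after transplant.

The design encodes the biology the downstream assays are meant to read out:

* CFSE-labelled donor T-cells home to the splenic white pulp and divide at a
  group-specific rate (mean divisions per 24 h); per-cell division counts are
  Poisson around the cumulative mean.
* White pulp grows in proportion to cumulative divisions (clonal expansion),
  and the whole spleen grows by the white-pulp increment, so allogeneic
  spleens enlarge while syngeneic ones do not.
* Qdot-labelled MSCs home to the marginal zone; allogeneic recipients
  recruit about twice as many MSCs to the spleen as syngeneic ones.

Numbers that the source biology does not pin down (cell counts per organ,
animal-to-animal size variation, exact expansion coefficient) are free
parameters of the design with defaults chosen to give effect sizes of the
same order as the group differences the assays are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GroundTruth, ImageVolume, InvalidDesignError, OrganMask
from .phantom import (
    CellPopulationSpec,
    PhantomSpec,
    RegionGeometry,
    generate_phantom,
)


@dataclass
class GroupParams:
    """Latent biology of one experimental group."""

    division_rate_per_day: float  # mean T-cell divisions per 24 h
    msc_multiplier: float = 1.0  # spleen MSC recruitment vs the syngeneic base


#: Default groups: syngeneic controls do not divide; allogeneic T-cells
#: divide about once per day; MSC treatment roughly halves the rate.  The
#: allogeneic spleen recruits ~2x the syngeneic MSC count.
DEFAULT_GROUPS = {
    "syn": GroupParams(division_rate_per_day=0.0, msc_multiplier=1.0),
    "allo": GroupParams(division_rate_per_day=1.0, msc_multiplier=2.0),
    "allo_msc": GroupParams(division_rate_per_day=0.5, msc_multiplier=2.0),
}


@dataclass
class CohortDesign:
    """Study layout plus the phantom parameters shared by all animals."""

    groups: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS)
    )
    timepoints_h: tuple[int, ...] = (24, 48, 72, 96)
    n_animals: int = 4

    grid_shape: tuple[int, int, int] = (18, 72, 72)
    envelope_radii_um: tuple[float, float, float] = (240.0, 250.0, 250.0)
    wp_radius_um: float = 140.0
    n_wp_nodules: int = 1
    mz_shell_voxels: int = 1

    n_tcells: int = 150
    n_mscs: int = 40
    tcell_I0: float = 200.0
    msc_I0: float = 220.0
    intensity_noise_cv: float = 0.1
    subsurface_fraction: float = 0.3
    subsurface_attenuation: float = 0.5

    #: fractional white-pulp volume growth per mean division
    wp_growth_per_division: float = 1.0
    #: animal-to-animal coefficient of variation on envelope radii
    animal_radius_cv: float = 0.03

    def __post_init__(self) -> None:
        if not self.groups:
            raise InvalidDesignError("cohort design names no groups")
        if not self.timepoints_h:
            raise InvalidDesignError("cohort design names no timepoints")
        if self.n_animals < 1:
            raise InvalidDesignError("need at least one animal per group")

    @property
    def base_wp_fraction(self) -> float:
        """Analytic white-pulp volume fraction of the base geometry."""
        wp = self.n_wp_nodules * self.wp_radius_um**3
        env = float(np.prod(self.envelope_radii_um))
        return wp / env


@dataclass
class AnimalRecord:
    """One imaged animal at one timepoint, with its latent parameters."""

    group: str
    timepoint_h: int
    animal: int
    volume: ImageVolume
    mask: OrganMask
    truth: GroundTruth
    params: dict


def simulate_cohort(design: CohortDesign, seed: int = 0) -> list[AnimalRecord]:
    """Generate one phantom spleen per animal per timepoint.

    The mean division count at time t is ``rate * t / 24``; white pulp volume
    is scaled by ``1 + wp_growth_per_division * mean_g`` and the envelope by
    the corresponding absolute white-pulp increment, so total spleen volume
    grows with proliferation.  The realised MSC count per spleen is Poisson
    with mean ``n_mscs * msc_multiplier``.
    """
    master = np.random.default_rng(seed)
    records: list[AnimalRecord] = []
    for group, params in design.groups.items():
        for timepoint in design.timepoints_h:
            for animal in range(design.n_animals):
                rng = np.random.default_rng(master.integers(2**31))
                mean_g = params.division_rate_per_day * timepoint / 24.0
                wp_mult = 1.0 + design.wp_growth_per_division * mean_g
                total_mult = 1.0 + design.base_wp_fraction * (wp_mult - 1.0)
                jitter = max(1.0 + rng.normal(0.0, design.animal_radius_cv), 0.5)
                envelope = tuple(
                    r * total_mult ** (1.0 / 3.0) * jitter
                    for r in design.envelope_radii_um
                )
                geometry = RegionGeometry(
                    envelope_radii_um=envelope,
                    n_wp_nodules=design.n_wp_nodules,
                    wp_radius_um=design.wp_radius_um * wp_mult ** (1.0 / 3.0) * jitter,
                    mz_shell_voxels=design.mz_shell_voxels,
                )
                spec = PhantomSpec(
                    grid_shape=design.grid_shape,
                    organ="spleen",
                    region_geometry=geometry,
                    rng_seed=int(rng.integers(2**31)),
                )
                n_msc = int(rng.poisson(design.n_mscs * params.msc_multiplier))
                populations = [
                    CellPopulationSpec(
                        n_cells=design.n_tcells,
                        region_label="white_pulp",
                        channel="green",
                        base_intensity_I0=design.tcell_I0,
                        generation_model=("poisson", mean_g) if mean_g > 0 else ("none", 0.0),
                        intensity_noise_cv=design.intensity_noise_cv,
                        subsurface_fraction=design.subsurface_fraction,
                        subsurface_attenuation=design.subsurface_attenuation,
                    ),
                    CellPopulationSpec(
                        n_cells=n_msc,
                        region_label="marginal_zone",
                        channel="red",
                        base_intensity_I0=design.msc_I0,
                        generation_model=("none", 0.0),
                        intensity_noise_cv=design.intensity_noise_cv,
                        subsurface_fraction=design.subsurface_fraction,
                        subsurface_attenuation=design.subsurface_attenuation,
                    ),
                ]
                volume, mask, truth = generate_phantom(spec, populations, rng)
                records.append(
                    AnimalRecord(
                        group=group,
                        timepoint_h=timepoint,
                        animal=animal,
                        volume=volume,
                        mask=mask,
                        truth=truth,
                        params={
                            "mean_generation": mean_g,
                            "wp_multiplier": wp_mult,
                            "total_multiplier": total_mult,
                            "n_mscs": n_msc,
                            "msc_multiplier": params.msc_multiplier,
                        },
                    )
                )
    return records
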