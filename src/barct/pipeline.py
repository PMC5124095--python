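"""End-to-end analysis of one pre/post scan pair.

Chains the whole carbonate-budget measurement: densitometry calibration,
carbonate thresholding, rigid registration of the post scan onto the
pre-scan frame, hull construction, the voxel partition, and the
standardized functional-group metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .functional_groups import FunctionalGroupRates, summarize_rates
from .register_partition import (
    DEFAULT_CLOSING_RADIUS_UM,
    LabelVolume,
    RigidTransform,
    partition_voxels,
    register_rigid,
    resample_to,
    solid_hull,
    threshold_carbonate,
)
from .volume_io import CalibrationCurve, Volume3D, attenuation_to_density

__all__ = ["PipelineConfig", "BarAnalysis", "analyze_bar_pair"]


@dataclass(frozen=True)
class PipelineConfig:
    threshold_method: str = "fraction"
    threshold_value: float | None = None
    closing_radius_um: float = DEFAULT_CLOSING_RADIUS_UM
    registration_max_iter: int = 200
    deployment_days: float = 658.0
    erode_voxels: int = 2
    min_feature_voxels: int = 1
    refine_registration: bool = True


@dataclass
class BarAnalysis:
    """Everything the pipeline derived from one scan pair."""

    labels: LabelVolume
    rates: FunctionalGroupRates
    transform: RigidTransform


def analyze_bar_pair(
    pre: Volume3D,
    post: Volume3D,
    pre_calibration: CalibrationCurve,
    post_calibration: CalibrationCurve | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> BarAnalysis:
    """Measure accretion, macroboring, grazing and microboring for one block.

    ``post_calibration`` defaults to the pre-scan curve when the two scan
    sessions shared a calibration.
    """
    post_calibration = post_calibration or pre_calibration
    thr = lambda v: threshold_carbonate(v, config.threshold_method, config.threshold_value)

    pre_mask = thr(pre)
    pre_hull = solid_hull(pre_mask, config.closing_radius_um, pre.pitch_um)

    def _partition(tfm):
        post_on_pre = resample_to(post, tfm, target=pre)
        post_mask = thr(post_on_pre)
        post_hull = solid_hull(post_mask, config.closing_radius_um, pre.pitch_um)
        labels = partition_voxels(
            pre_mask,
            post_mask,
            pre_hull,
            post_hull,
            pre.pitch_um,
            min_feature_voxels=config.min_feature_voxels,
        )
        return post_on_pre, labels

    transform = register_rigid(moving=post, fixed=pre, max_iter=config.registration_max_iter)
    post_on_pre, labels = _partition(transform)

    if config.refine_registration:
        # second pass: exclude the regions that changed between scans from
        # the similarity metric, removing their pull on the alignment
        from scipy import ndimage

        changed = (
            labels.mask("accretion") | labels.mask("macroboring_void") | labels.mask("grazed")
        )
        changed = ndimage.binary_dilation(
            changed, ndimage.generate_binary_structure(3, 1), iterations=3
        )
        transform = register_rigid(
            moving=post,
            fixed=pre,
            max_iter=config.registration_max_iter,
            fixed_mask=~changed,
            init=transform,
        )
        post_on_pre, labels = _partition(transform)

    pre_density = attenuation_to_density(pre, pre_calibration)
    post_density = attenuation_to_density(post_on_pre, post_calibration)
    rates = summarize_rates(
        labels,
        pre_density,
        post_density,
        deployment_days=config.deployment_days,
        erode_voxels=config.erode_voxels,
    )
    return BarAnalysis(labels=labels, rates=rates, transform=transform)
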