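"""Synthetic chromatograms and probe-level arrays with planted structure.

The generator emulates the two data layers of a dual fingerprinting
study of herbal extracts:

* **Chromatograms** — a set of samples in a small number of
  phytogeographic groups (default 7/5/1) sharing a backbone of Gaussian
  peaks whose amplitudes are scaled per group, plus group-exclusive
  marker peaks (the "one constituent only present in one origin"
  pattern), retention-time jitter, a slow polynomial baseline drift and
  i.i.d. Gaussian detector noise.

* **Probe-level expression arrays** — probesets of ~11 probes each, with
  a per-probeset baseline, per-probe affinity offsets, condition effects
  (a treatment-shared repressed module and group-specific modules),
  multiplicative per-array effects and lognormal (Gaussian on log2)
  noise.

Every random draw descends from one seed through per-sample spawn keys,
so regenerating with more samples leaves earlier samples bit-identical.
Ground truth (group labels, marker positions, planted effects) is
returned alongside the data so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chrom import Chromatogram
from .exprproc import ProbeMatrix, ProbesetMap

__all__ = [
    "SyntheticDesign",
    "ExprDesign",
    "GroundTruth",
    "generate_chromatograms",
    "generate_probe_arrays",
]


@dataclass
class GroundTruth:
    """What was planted: labels, marker positions, differential genes."""

    sample_labels: list[int]
    marker_peak_rts: dict[str, list[float]] = field(default_factory=dict)
    backbone_rts: list[float] = field(default_factory=list)
    de_gene_ids: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SyntheticDesign:
    """Design of a synthetic chromatogram set.

    Defaults mirror a 13-sample, 3-group study (7/5/1) with one
    group-exclusive marker peak per group on a 20-peak shared backbone.
    ``within_group_cv`` controls within-group chemical variability as a
    lognormal coefficient of variation of peak heights.

    Two kinds of between-group amplitude structure are planted.
    ``amplitude_group_scale`` multiplies a whole group's traces (overall
    extract concentration; visible to raw peak heights, invisible to
    within-sample ratios). ``group_composition_sd`` draws a per-group,
    per-backbone-peak relative-composition signature (lognormal, log2-sd
    in these units): chemotypes share constituents but at different
    relative levels, which is exactly the structure ratio features are
    built to detect.
    """

    group_sizes: tuple[int, ...] = (7, 5, 1)
    group_names: tuple[str, ...] | None = None
    n_backbone_peaks: int = 20
    n_marker_peaks_per_group: int = 1
    rt_range: tuple[float, float] = (0.5, 30.0)
    rt_jitter_sd: float = 0.05
    amplitude_group_scale: tuple[float, ...] = (1.0, 0.65, 1.4)
    group_composition_sd: float = 0.4
    noise_sd: float = 1.0
    baseline_amplitude: float = 5.0
    height_range: tuple[float, float] = (30.0, 120.0)
    width_range: tuple[float, float] = (0.06, 0.12)
    within_group_cv: float = 0.05
    n_points: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must all be >= 1")
        if self.rt_jitter_sd < 0:
            raise ValueError("rt_jitter_sd must be >= 0")
        if len(self.amplitude_group_scale) != len(self.group_sizes):
            raise ValueError("need one amplitude factor per group")
        if any(a <= 0 for a in self.amplitude_group_scale):
            raise ValueError("amplitude factors must be positive")
        if self.group_names is None:
            self.group_names = tuple(f"group{g}" for g in range(len(self.group_sizes)))
        if len(self.group_names) != len(self.group_sizes):
            raise ValueError("need one group name per group")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def n_total_peaks(self) -> int:
        return self.n_backbone_peaks + len(self.group_sizes) * self.n_marker_peaks_per_group


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_chromatograms(
    design: SyntheticDesign,
) -> tuple[list[Chromatogram], GroundTruth]:
    """Generate one chromatogram per sample plus the planted ground truth.

    Peak apex positions are evenly spaced across ``rt_range`` with an
    edge margin; generation fails explicitly if the range cannot hold all
    requested peaks at >= 3 sigma (peak width) separation. Marker peaks
    are interleaved with the backbone by a seeded permutation so they do
    not cluster at one end of the trace.
    """
    lo, hi = design.rt_range
    wmax = design.width_range[1]
    n_total = design.n_total_peaks
    margin = 3.0 * wmax
    usable = (hi - lo) - 2 * margin
    if n_total > 1:
        spacing = usable / (n_total - 1)
    else:
        spacing = usable
    if usable <= 0 or spacing < 3.0 * wmax:
        raise ValueError(
            f"rt_range {design.rt_range} too narrow for {n_total} peaks at "
            f">= 3 sigma separation (needs spacing >= {3 * wmax:.3f})"
        )

    struct = _rng(design.seed, 0)
    positions = np.linspace(lo + margin, hi - margin, n_total)
    widths = struct.uniform(*design.width_range, size=n_total)
    base_heights = struct.uniform(*design.height_range, size=n_total)
    n_groups_ = len(design.group_sizes)
    composition = np.exp2(
        struct.normal(0.0, design.group_composition_sd, size=(n_groups_, n_total))
        if design.group_composition_sd > 0
        else np.zeros((n_groups_, n_total))
    )
    perm = struct.permutation(n_total)
    backbone_idx = perm[: design.n_backbone_peaks]
    n_groups = len(design.group_sizes)
    marker_idx = {
        g: perm[
            design.n_backbone_peaks + g * design.n_marker_peaks_per_group :
            design.n_backbone_peaks + (g + 1) * design.n_marker_peaks_per_group
        ]
        for g in range(n_groups)
    }

    rt = np.linspace(lo, hi, design.n_points)
    xnorm = (rt - lo) / (hi - lo)
    labels: list[int] = []
    for g, size in enumerate(design.group_sizes):
        labels.extend([g] * size)

    chroms: list[Chromatogram] = []
    for i, g in enumerate(labels):
        rng = _rng(design.seed, 1, i)
        jitter = rng.normal(0.0, design.rt_jitter_sd, size=n_total)
        height_noise = (
            np.exp(rng.normal(0.0, design.within_group_cv, size=n_total))
            if design.within_group_cv > 0
            else np.ones(n_total)
        )
        scale = design.amplitude_group_scale[g]
        present = np.zeros(n_total, dtype=bool)
        present[backbone_idx] = True
        present[marker_idx[g]] = True
        trace = np.zeros_like(rt)
        for p in np.flatnonzero(present):
            h = base_heights[p] * composition[g, p] * scale * height_noise[p]
            mu = positions[p] + jitter[p]
            trace += h * np.exp(-0.5 * ((rt - mu) / widths[p]) ** 2)
        if design.baseline_amplitude > 0:
            coefs = rng.uniform(-1.0, 1.0, size=4)
            b = np.polyval(coefs, xnorm)
            b = b - b.min()
            peak = b.max()
            if peak > 0:
                b = b / peak * design.baseline_amplitude
            trace += b
        if design.noise_sd > 0:
            trace += rng.normal(0.0, design.noise_sd, size=rt.size)
        chroms.append(
            Chromatogram(
                rt=rt,
                intensity=trace,
                sample_id=f"S{i + 1:02d}",
                technique="synthetic",
                group=design.group_names[g],
            )
        )

    truth = GroundTruth(
        sample_labels=labels,
        marker_peak_rts={
            design.group_names[g]: [float(positions[p]) for p in marker_idx[g]]
            for g in range(n_groups)
        },
        backbone_rts=[float(positions[p]) for p in sorted(backbone_idx)],
    )
    return chroms, truth


@dataclass
class ExprDesign:
    """Design of a synthetic probe-level expression experiment.

    Conditions default to a 4-control / 6-China+Europe / 4-USA / 2-India
    array layout. ``shared_effect_genes`` maps probeset index -> log2
    effect applied in every treated (non-control) condition (the shared
    repressed-module analogue); ``group_specific_genes`` maps condition ->
    {probeset index -> log2 effect} for effects exclusive to one group.
    """

    n_probesets: int = 500
    probes_per_set: int = 11
    arrays_per_condition: dict[str, int] = field(
        default_factory=lambda: {"control": 4, "china_europe": 6, "usa": 4, "india": 2}
    )
    control_condition: str = "control"
    shared_effect_genes: dict[int, float] = field(
        default_factory=lambda: {i: -1.0 for i in range(25)}
    )
    group_specific_genes: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"usa": {i: 1.0 for i in range(25, 40)}}
    )
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    probe_affinity_sd: float = 0.7
    array_scale_sd: float = 0.1
    noise_sd: float = 0.25
    bg_mean: float = 40.0
    bg_sd: float = 8.0
    frac_unexpressed: float = 0.5
    unexpressed_log2_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets < 1 or self.probes_per_set < 1:
            raise ValueError("counts must be >= 1")
        if any(n < 1 for n in self.arrays_per_condition.values()):
            raise ValueError("replicate counts must be >= 1")
        if self.control_condition not in self.arrays_per_condition:
            raise ValueError("control condition missing from arrays_per_condition")
        sets = [set(self.shared_effect_genes)] + [
            set(m) for m in self.group_specific_genes.values()
        ]
        total = sum(len(s) for s in sets)
        union = set().union(*sets) if sets else set()
        if len(union) != total:
            raise ValueError("planted effect index sets must be disjoint")
        if union and max(union) >= self.n_probesets:
            raise ValueError("planted effect index out of range")
        for cond in self.group_specific_genes:
            if cond not in self.arrays_per_condition or cond == self.control_condition:
                raise ValueError(f"group-specific effects for unknown condition {cond!r}")

    @property
    def conditions(self) -> list[str]:
        out = []
        for cond, n in self.arrays_per_condition.items():
            out.extend([cond] * n)
        return out


def generate_probe_arrays(
    design: ExprDesign,
) -> tuple[ProbeMatrix, ProbesetMap, GroundTruth]:
    """Generate probe-level intensities, the probe->probeset map and truth.

    probe intensity = (2^(probeset baseline + probe affinity + condition
    effect + N(0, noise_sd)) + optical background) x array factor, with
    the array factor lognormal with log-sd ``array_scale_sd`` and the
    background normal (mean ``bg_mean``, sd ``bg_sd``, floored just above
    zero). The additive background is what the normal+exponential
    convolution correction is built to remove; without it that stage
    would systematically distort low-intensity probes. Deterministic per
    array given the seed.
    """
    struct = _rng(design.seed, 10)
    baselines = struct.normal(design.baseline_mean, design.baseline_sd, design.n_probesets)
    affinities = struct.normal(
        0.0, design.probe_affinity_sd, (design.n_probesets, design.probes_per_set)
    )
    # a realistic fraction of probesets is not expressed (signal near zero,
    # intensity dominated by optical background); planted-effect genes are
    # kept expressed
    planted = set(design.shared_effect_genes) | {
        i for m in design.group_specific_genes.values() for i in m
    }
    eligible = np.array([i for i in range(design.n_probesets) if i not in planted])
    n_off = min(int(round(design.frac_unexpressed * design.n_probesets)), eligible.size)
    off_idx = struct.choice(eligible, size=n_off, replace=False) if n_off else np.array([], int)
    baselines[off_idx] = struct.normal(design.unexpressed_log2_mean, 0.5, size=n_off)

    ps_ids = [f"ps{i:04d}" for i in range(design.n_probesets)]
    probe_ids = [
        f"{ps}_p{j:02d}" for i, ps in enumerate(ps_ids) for j in range(design.probes_per_set)
    ]
    mapping = {f"{ps}_p{j:02d}": ps for ps in ps_ids for j in range(design.probes_per_set)}

    conditions = design.conditions
    array_ids = []
    counters: dict[str, int] = {}
    for cond in conditions:
        counters[cond] = counters.get(cond, 0) + 1
        array_ids.append(f"{cond}_{counters[cond]}")

    n_probes = design.n_probesets * design.probes_per_set
    values = np.empty((n_probes, len(conditions)))
    log2_signal = baselines[:, None] + affinities  # probesets x probes_per_set
    for a, cond in enumerate(conditions):
        rng = _rng(design.seed, 11, a)
        effect = np.zeros(design.n_probesets)
        if cond != design.control_condition:
            for idx, fc in design.shared_effect_genes.items():
                effect[idx] += fc
            for idx, fc in design.group_specific_genes.get(cond, {}).items():
                effect[idx] += fc
        log2v = (log2_signal + effect[:, None]).ravel()
        log2v = log2v + rng.normal(0.0, design.noise_sd, size=n_probes)
        factor = float(np.exp(rng.normal(0.0, design.array_scale_sd)))
        bg = np.maximum(rng.normal(design.bg_mean, design.bg_sd, size=n_probes), 1e-3)
        values[:, a] = (np.exp2(log2v) + bg) * factor

    cond_levels = list(design.arrays_per_condition)
    truth = GroundTruth(
        sample_labels=[cond_levels.index(c) for c in conditions],
        de_gene_ids=_planted_contrasts(design, ps_ids),
    )
    matrix = ProbeMatrix(values, probe_ids, array_ids, condition=list(conditions))
    return matrix, ProbesetMap(mapping), truth


def _planted_contrasts(design: ExprDesign, ps_ids: list[str]) -> dict[str, dict[str, float]]:
    shared = {ps_ids[i]: fc for i, fc in design.shared_effect_genes.items()}
    out = {"control_vs_all": dict(shared)}
    for cond, effects in design.group_specific_genes.items():
        d = dict(shared)
        d.update({ps_ids[i]: fc for i, fc in effects.items()})
        out[f"control_vs_{cond}"] = d
    return out
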