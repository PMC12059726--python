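"""Shared container types used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed network order used everywhere a 7x7 matrix is produced.
NETWORKS = ("SMN", "VAN", "VN", "DAN", "DMN", "FPN", "SC")


@dataclass
class SubjectRecord:
    """One subject: identifiers, covariates, clinical scores, regional time series.

    ``timeseries`` is a T x R array with one column per atlas region, in
    region_id order. ``hamd``/``hama`` may be None to model missing
    assessments. ``group`` records the planted group label (1 or 2) for
    simulated subjects; it is generator metadata, not an input to grouping.
    """

    subject_id: str
    site: str
    age: float
    sex: str  # 'M' or 'F'
    education: float
    fd: float
    hamd: int | None
    hama: int | None
    quality_score: int
    timeseries: np.ndarray
    group: int | None = None


@dataclass
class EffectSpec:
    """Planted-effect description for the synthetic generators.

    network_pairs: between-network blocks that receive ``delta`` (on the
    correlation scale) in group 2. site_offsets/site_scales define per-site
    affine transforms of the latent correlation (FC-scale site effects).
    """

    network_pairs: list[tuple[str, str]] = field(default_factory=lambda: [("SC", "VN")])
    delta: float = 0.0
    n_planted_genes: int = 0
    spatial_corr_length: float = 20.0
    site_offsets: dict[str, float] = field(default_factory=dict)
    site_scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spatial_corr_length <= 0:
            raise ValueError("spatial_corr_length must be > 0")


@dataclass
class DonorTable:
    """Microarray-style tissue samples for one donor.

    samples: DataFrame with columns sample_id, x, y, z, structure_class,
    hemisphere, source_region (generator metadata).
    intensities / above_background: DataFrames indexed like ``samples``
    (sample_id) with one column per probe_id.
    """

    donor_id: str
    samples: pd.DataFrame
    intensities: pd.DataFrame
    above_background: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.shape != self.above_background.shape:
            raise ValueError("intensities and above_background must have the same shape")


@dataclass
class ProbeTable:
    """Probe -> gene mapping plus an optional per-sample reference profile.

    probes: DataFrame with columns probe_id, gene_symbol (and, for synthetic
    data, an is_planted flag). reference_profile: DataFrame indexed by
    gene_symbol, one column per pooled sample_id; stands in for RNA-seq.
    """

    probes: pd.DataFrame
    reference_profile: pd.DataFrame | None = None


@dataclass
class ExpressionMatrix:
    """Region x gene expression after processing; left hemisphere only."""

    data: pd.DataFrame  # rows indexed by region_id, columns = gene symbols
    missing_regions: list[int] = field(default_factory=list)


@dataclass
class EdgeStatMap:
    """Edge-wise group-contrast statistics: symmetric t and p matrices."""

    t: np.ndarray
    p: np.ndarray
    df: int
    contrast: str = ""


@dataclass
class NBSComponent:
    edges: list[tuple[int, int]]
    size: int
    p_value: float


@dataclass
class NBSResult:
    components: list[NBSComponent]
    null_max_size: np.ndarray
    edge_p: float
    alpha: float
    n_perm: int
    t_threshold: float

    @property
    def significant(self) -> list[NBSComponent]:
        return [c for c in self.components if c.p_value < self.alpha]


@dataclass
class PLSModel:
    """SIMPLS fit: weights/scores per component and variance bookkeeping."""

    weights: np.ndarray        # p x K gene weight vectors
    scores: np.ndarray         # n x K orthonormal region score vectors
    x_loadings: np.ndarray     # p x K
    y_loadings: np.ndarray     # K
    var_y: np.ndarray          # fraction of response variance per component
    var_x: np.ndarray          # fraction of predictor variance per component
    y: np.ndarray              # standardized response used for the fit
    n_components: int
    selected: int | None = None


@dataclass
class SurrogateEnsemble:
    """Spatial-autocorrelation-preserving surrogate response maps."""

    maps: np.ndarray            # N x R
    variogram_fit: pd.DataFrame  # per-surrogate kernel choice and SSE
    distance_bins: np.ndarray
    empirical_variogram: np.ndarray


@dataclass
class GeneSetCollection:
    """Named gene sets: term -> (description, genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())
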