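"""Results object for the clustering-enabled regression."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import posterior
from .model import ClusterTrajectoryModel, PosteriorSamples


class ClusterTrajectoryResults:
    """Retained Gibbs draws plus the inference helpers built on them."""

    def __init__(self, model: ClusterTrajectoryModel, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    # -- clusters -----------------------------------------------------------

    def mean_labels(self) -> np.ndarray:
        """R x K posterior label frequencies (mbar)."""
        return self.assign_clusters().mbar

    def assign_clusters(self, region_ids=None) -> posterior.ClusterAssignment:
        return posterior.assign_clusters(self.samples, region_ids=region_ids)

    def coclustering(self) -> np.ndarray:
        """R x R posterior co-clustering frequencies (label-switching-proof
        diagnostic)."""
        lab = self.samples.labels  # (n, R)
        return (lab[:, :, None] == lab[:, None, :]).mean(axis=0)

    def posterior_mean_B(self) -> np.ndarray:
        return self.samples.B.mean(axis=0)

    # -- trajectories -------------------------------------------------------

    def trajectories(
        self, ages: np.ndarray, pairs: list | None = None
    ) -> posterior.TrajectoryWithBands:
        return posterior.estimate_trajectories(
            self.samples, ages, self.model.design, pairs=pairs
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        assign = self.assign_clusters()
        frame = assign.to_frame()
        frame["n_draws"] = self.samples.n_draws
        return frame
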