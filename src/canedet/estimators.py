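"""scikit-learn style estimator facade.

``StemNodeDetector`` wraps build → train → predict in the familiar
``fit``/``predict`` shape (get_params/set_params compatible, fitted
attributes with trailing underscores), so the detector composes with
sklearn tooling; ``LampPruner`` exposes pruning as a transform over a
fitted detector.  The underlying library modules remain the real
implementation surface.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .assembly import ModelSpec, build_model, complexity_report
from .boxgeom import ShapeIoUParams
from .lamp import PruneSchedule, prune
from .suppress import SuppressConfig, SuppressMode
from .train import RunConfig, evaluate_model, finetune, predict, train

__all__ = ["StemNodeDetector", "LampPruner"]


class StemNodeDetector(BaseEstimator):
    """Anchor-free stem-node detector with shape-aware regression.

    Parameters mirror the training recipe; ``fit(X, y)`` takes a list of
    HxWx3 uint8 images and per-image lists of ground-truth
    :class:`~canedet.boxgeom.Box`.  ``predict(X)`` returns per-image
    :class:`~canedet.suppress.Detection` lists after soft suppression.
    """

    def __init__(self, variant="ours", input_size=128, epochs=12, batch=4,
                 lr0=0.01, seed=0, shape_scale=0.0, shape_alpha=1.5,
                 omega_weight=0.5, suppress_mode="soft-gaussian-shape",
                 sigma=0.5, nt=0.5, conf_threshold=0.1):
        self.variant = variant
        self.input_size = input_size
        self.epochs = epochs
        self.batch = batch
        self.lr0 = lr0
        self.seed = seed
        self.shape_scale = shape_scale
        self.shape_alpha = shape_alpha
        self.omega_weight = omega_weight
        self.suppress_mode = suppress_mode
        self.sigma = sigma
        self.nt = nt
        self.conf_threshold = conf_threshold

    def _run_config(self) -> RunConfig:
        return RunConfig(
            input_size=self.input_size, epochs=self.epochs, batch=self.batch,
            lr0=self.lr0, seed=self.seed, variant=self.variant,
            loss=ShapeIoUParams(self.shape_scale, self.shape_alpha,
                                self.omega_weight),
            suppress=SuppressConfig(mode=SuppressMode(self.suppress_mode),
                                    nt=self.nt, sigma=self.sigma),
            conf_threshold=self.conf_threshold)

    def fit(self, X, y):
        if len(X) != len(y):
            raise ValueError("images and box lists differ in length")
        cfg = self._run_config()
        self.net_ = build_model(ModelSpec(variant=self.variant, seed=self.seed))
        data = list(zip(X, y))
        self.history_ = train(self.net_, data, [], cfg)
        self.complexity_ = complexity_report(self.net_).as_dict()
        return self

    def predict(self, X):
        self._check_fitted()
        return predict(self.net_, X, self._run_config())

    def score(self, X, y):
        """mAP50 on the given images/boxes."""
        self._check_fitted()
        return float(evaluate_model(self.net_, list(zip(X, y)),
                                    self._run_config()).map50)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("call fit() first")


class LampPruner(BaseEstimator):
    """LAMP channel pruning as an estimator transform.

    ``fit`` prunes a fitted detector's network toward ``speed_up`` and
    optionally fine-tunes on the provided data.
    """

    def __init__(self, speed_up=2.0, steps=40, max_sparsity=1.0, reg=5e-4,
                 finetune_epochs=0, input_size=640):
        self.speed_up = speed_up
        self.steps = steps
        self.max_sparsity = max_sparsity
        self.reg = reg
        self.finetune_epochs = finetune_epochs
        self.input_size = input_size

    def fit(self, detector: StemNodeDetector, data=None):
        detector._check_fitted()
        sched = PruneSchedule(steps=self.steps, speed_up=self.speed_up,
                              max_sparsity=self.max_sparsity, reg=self.reg,
                              input_size=self.input_size)
        _, self.report_ = prune(detector.net_, sched)
        if self.finetune_epochs and data:
            finetune(detector.net_, data, [], detector._run_config(),
                     epochs=self.finetune_epochs)
        return self
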