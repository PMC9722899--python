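"""The scikit-learn-style front end.

``LodeSTAR`` bundles network construction, single-crop self-distillation
training, pooled single-object prediction, and multi-object detection behind
the familiar ``fit`` / ``predict`` estimator contract, so it composes with
sklearn tooling (``get_params``/``set_params``, cloning, pipelines).

Typical use::

    model = LodeSTAR(n_batches=5000, random_state=0)
    model.fit(crop)                    # one 2D crop of one object
    xy = model.predict(test_images)    # (n, 2) sub-pixel positions
    table = model.detect(big_image)    # multi-object detections DataFrame
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .detect import DetectParams, detect as _detect
from .model import NetworkConfig, build_network, forward, pooled_prediction
from .simulate import ComplexField, OpticalConfig
from .training import TrainConfig, normalize_intensity, train as _train

__all__ = ["LodeSTAR"]


class LodeSTAR(BaseEstimator):
    """Single-shot self-supervised object detector.

    Parameters mirror the training protocol: the network (``channels``,
    ``pre_pool_layers``, ``post_pool_layers``), the optimization
    (``n_batches``, ``batch_size``, ``learning_rate``), the transformation
    group (``translation_range`` px, ``rotations``, ``reflections``, and the
    holographic extras ``dz_range`` in um and ``ln_scale_range``), and the
    detection defaults (``alpha``, ``quantile``).

    Fitted attributes: ``network_``, ``network_config_``, ``train_config_``,
    ``loss_history_``.
    """

    def __init__(
        self,
        channels: int = 32,
        pre_pool_layers: int = 3,
        post_pool_layers: int = 8,
        n_batches: int = 5000,
        batch_size: int = 8,
        learning_rate: float = 1e-3,
        translation_range: float = 8.0,
        rotations: bool = True,
        reflections: bool = True,
        dz_range: float = 0.0,
        ln_scale_range: float = 0.0,
        alpha: float = 0.1,
        quantile: float = 0.99,
        optics: OpticalConfig | None = None,
        random_state: int = 0,
    ):
        self.channels = channels
        self.pre_pool_layers = pre_pool_layers
        self.post_pool_layers = post_pool_layers
        self.n_batches = n_batches
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.translation_range = translation_range
        self.rotations = rotations
        self.reflections = reflections
        self.dz_range = dz_range
        self.ln_scale_range = ln_scale_range
        self.alpha = alpha
        self.quantile = quantile
        self.optics = optics
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            n_batches=self.n_batches,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            translation_range=self.translation_range,
            rotations=self.rotations,
            reflections=self.reflections,
            dz_range=self.dz_range,
            ln_scale_range=self.ln_scale_range,
            seed=self.random_state,
        )

    @staticmethod
    def _in_channels(crop) -> int:
        return 2 if isinstance(crop, ComplexField) else 1

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a single object crop (or a list of crops).

        ``X``: 2D intensity crop, a ``ComplexField``, or a list of either.
        ``y`` is ignored — training is self-supervised.
        """
        crops = X if isinstance(X, (list, tuple)) else [X]
        cfg = self._train_config()
        self.train_config_ = cfg
        self.network_config_ = NetworkConfig(
            in_channels=self._in_channels(crops[0]),
            channels=self.channels,
            pre_pool_layers=self.pre_pool_layers,
            post_pool_layers=self.post_pool_layers,
            extra_channels=cfg.extra_channels,
        )
        rng = np.random.default_rng(self.random_state)
        self.network_ = build_network(self.network_config_, rng)
        optics = self.optics or (OpticalConfig() if cfg.dz_range > 0 else None)
        self.loss_history_ = _train(
            X if isinstance(X, (list, tuple)) else crops[0],
            cfg,
            self.network_,
            optics=optics,
            rng=rng,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Pooled single-object predictions for a batch of crops.

        Returns ``(n, 2 + extras)`` — x, y in px (top-left convention),
        then any extra channels (z in um, log signal scale).
        """
        check_is_fitted(self, "network_")
        crops = X if isinstance(X, (list, tuple)) else [X]
        out = []
        for crop in crops:
            if isinstance(crop, ComplexField):
                img = crop.planes()
            else:
                img = normalize_intensity(np.asarray(crop, dtype=float))
            stack = forward(self.network_, img)
            p = pooled_prediction(stack, border_margin=3)
            out.append([p.x, p.y, *p.extras])
        return np.asarray(out)

    def detect(self, image, **overrides) -> pd.DataFrame:
        """Multi-object detection on an arbitrarily large image.

        Keyword overrides go to :class:`~lodestar.detect.DetectParams`
        (``alpha``, ``quantile``, ``prominence``, ``window``).
        """
        check_is_fitted(self, "network_")
        params = DetectParams(
            alpha=overrides.pop("alpha", self.alpha),
            quantile=overrides.pop("quantile", self.quantile),
            **overrides,
        )
        return _detect(self.network_, image, params)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        from .io import save_network

        check_is_fitted(self, "network_")
        save_network(path, self.network_, self.network_config_, extra_meta=self.get_params(deep=False) | {"optics": None})

    @classmethod
    def from_file(cls, path) -> "LodeSTAR":
        from .io import load_network

        network, netcfg, meta = load_network(path)
        meta = {k: v for k, v in meta.items() if k != "optics"}
        est = cls(**meta) if meta else cls()
        est.network_ = network
        est.network_config_ = netcfg
        est.train_config_ = est._train_config()
        est.loss_history_ = {"loss_a": [], "loss_b": []}
        return est
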