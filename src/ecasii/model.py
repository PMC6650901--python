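"""Model/Results front end for the whole method.

``MGCAModel`` bundles the training conditions — a scene source (a synthetic
scene spec or pre-built labeled scenes), the automaton settings and the
evolutionary budget.  ``fit`` runs the differential evolution and returns an
``MGCAResults`` carrying the fitted rule table, the cost trace and
diagnostics; ``segment``, ``classify_cube`` and ``summary`` hang off the
results object.

    >>> model = MGCAModel.from_scene_spec(SceneSpec(N=5, seed=3),
    ...                                   de=DEConfig(NP=20, max_generations=30))
    >>> res = model.fit()
    >>> print(res.summary())
    >>> segmented = res.segment(cube)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AccuracyReport, ClassifierSpec, accuracy, classify_pixels, split_train_test
from .core import LabelMap, SpectralImage, normalize
from .de import DEConfig, EvolutionTrace, FixedSceneSource, SyntheticSceneSource, evolve
from .mgca import UpdateConfig, mean_neighbor_angle, run_mgca
from .rules import RuleSet
from .synthgen import SceneBundle, SceneSpec

__all__ = ["MGCAModel", "MGCAResults"]


@dataclass
class MGCAModel:
    """An evolvable multi-gradient cellular automaton.

    Parameters
    ----------
    scene_source : object with ``draw(seed) -> SceneBundle``
        Supplier of labeled training scenes.
    de : DEConfig
        Evolutionary budget and automaton settings (K iterations, f_th, the
        intra/inter cost sampling sizes).
    """

    scene_source: object
    de: DEConfig = field(default_factory=DEConfig)

    @classmethod
    def from_scene_spec(cls, spec: SceneSpec, de: DEConfig | None = None) -> "MGCAModel":
        """Train on freshly generated synthetic scenes from one spec template."""
        return cls(scene_source=SyntheticSceneSource(spec), de=de or DEConfig())

    @classmethod
    def from_scenes(cls, bundles: list[SceneBundle], de: DEConfig | None = None) -> "MGCAModel":
        """Train on a fixed collection of labeled scenes."""
        return cls(scene_source=FixedSceneSource(bundles), de=de or DEConfig())

    def fit(self, seed: int | None = None, progress=None) -> "MGCAResults":
        """Evolve the rule table; returns the fitted results object."""
        cfg = self.de
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=int(seed))
        rules, trace = evolve(cfg, self.scene_source, progress=progress)
        return MGCAResults(model=self, config=cfg, rules=rules, trace=trace)


@dataclass
class MGCAResults:
    """A fitted rule table plus its evolution diagnostics."""

    model: MGCAModel
    config: DEConfig
    rules: RuleSet
    trace: EvolutionTrace

    @property
    def params(self) -> np.ndarray:
        """The genome (flattened rule table)."""
        return self.rules.to_genome()

    @property
    def best_cost(self) -> float:
        return self.trace.best_cost

    def rules_frame(self) -> pd.DataFrame:
        cols = ["mod3", "mod5", "mod7", "phi5", "phi7", "theta"]
        return pd.DataFrame(self.rules.table, columns=cols)

    def segment(
        self, img: SpectralImage, iterations: int | None = None, callback=None
    ) -> SpectralImage:
        """Run the fitted automaton on a (normalized) cube."""
        upd = self.config.update
        if iterations is not None:
            upd = UpdateConfig(
                f_th=upd.f_th, iterations=iterations, refine_steps=upd.refine_steps
            )
        return run_mgca(normalize(img), self.rules, upd, callback=callback)

    def classify_cube(
        self,
        img: SpectralImage,
        truth: LabelMap,
        train_per_class: int | None = 25,
        train_total: int | None = None,
        classifier: ClassifierSpec | None = None,
        split_seed: int | None = 0,
        iterations: int | None = None,
    ) -> tuple[AccuracyReport, AccuracyReport]:
        """Paired evaluation: classifier on the raw cube vs on the segmented
        cube, same stratified split.  Returns ``(raw_report, seg_report)``."""
        train, test = split_train_test(
            truth,
            per_class=train_per_class if train_total is None else None,
            total=train_total,
            seed=split_seed,
        )
        classifier = classifier or ClassifierSpec()
        raw_norm = normalize(img)
        pred_raw = classify_pixels(raw_norm, train, truth, classifier)
        seg = self.segment(img, iterations=iterations)
        pred_seg = classify_pixels(seg, train, truth, classifier)
        return (
            accuracy(pred_raw, truth, mask=test),
            accuracy(pred_seg, truth, mask=test),
        )

    def homogeneity_gain(self, img: SpectralImage, mask: np.ndarray | None = None) -> float:
        """Reduction of the mean 8-neighbor spectral angle due to segmentation."""
        before = mean_neighbor_angle(normalize(img), mask)
        after = mean_neighbor_angle(self.segment(img), mask)
        return before - after

    def save_rules(self, path) -> None:
        self.rules.to_json(path)

    def summary(self) -> str:
        """Human-readable fit summary in the style of statistical models."""
        tr = self.trace.to_frame()
        lines = [
            "Evolved multi-gradient cellular automaton",
            "=" * 48,
            f"rules:              {self.rules.n_rules} (genome length "
            f"{self.rules.genome_length})",
            f"population (NP):    {self.config.NP}",
            f"F / CR:             {self.config.F} / {self.config.CR}",
            f"evaluation mode:    {self.config.mode}",
            f"CA iterations (K):  {self.config.update.iterations}",
            f"generations run:    {len(tr)}",
            f"final best cost:    {self.best_cost:.6f}",
        ]
        if len(tr):
            lines.append(
                f"cost trajectory:    best {tr.best_cost.iloc[0]:.4f} -> "
                f"{tr.best_cost.iloc[-1]:.4f}, mean {tr.mean_cost.iloc[-1]:.4f}"
            )
        lines.append("-" * 48)
        lines.append("rule table (first 5 rows):")
        lines.append(self.rules_frame().head().round(4).to_string())
        return "\n".join(lines)
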