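import numpy as np
import pytest

from orchardfusion.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def eight_scenes():
    """Eight 128x128 scenes, alternating phenological stage."""
    return [generate_scene(SceneSpec(
        width=128, height=128,
        stage="flowering" if i % 2 == 0 else "young_fruit",
        seed=i)) for i in range(8)]


@pytest.fixture(scope="session")
def overfit_run(eight_scenes):
    """Train the dual-attention model to overfit the eight scenes.

    Shared session-wide: training is the expensive step, and several tests
    inspect the same trained model (loss curve, mask prediction, metrics).
    """
    from orchardfusion.segmentation import (ModelConfig, TrainConfig, build_model,
                                            evaluate_segmentation, predict_mask, train)

    model = build_model(ModelConfig(n_classes=5, backbone="tiny16",
                                    input_size=128), seed=0)
    tc = TrainConfig(epochs=100, batch_size=4, learning_rate=0.01,
                     optimizer="adam", val_fraction=0.0, seed=0, max_steps=200)
    model, history = train(model, eight_scenes, tc)
    preds = [predict_mask(model, s.image) for s in eight_scenes]
    metrics = evaluate_segmentation(preds, [s.mask for s in eight_scenes], 5)
    return {"model": model, "history": history, "preds": preds,
            "metrics": metrics, "scenes": eight_scenes, "steps": 200}
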