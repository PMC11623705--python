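import numpy as np
import pytest

from patlite.finetune import ClassifierConfig
from patlite.synthetic_data import CohortSpec, generate_cohort
from patlite.transformer_core import make_config
from patlite.workflows import finetune_on_cohort

TWO_DAYS = 2_880  # a short (2-day) horizon keeps unit tests fast


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n=40, T=TWO_DAYS, base_rate=0.3,
                                      wake_shift_minutes=180, seed=11))


@pytest.fixture(scope="session")
def tiny_cfg():
    return make_config("tiny", T=TWO_DAYS)


@pytest.fixture(scope="session")
def trained_clf(small_cohort, tiny_cfg):
    """A quickly fine-tuned tiny classifier shared by explainability tests."""
    clf, history = finetune_on_cohort(
        small_cohort, ClassifierConfig(mode="FT", epochs=3, batch_size=8, seed=5),
        tiny_cfg)
    return clf


def fd_gradcheck(build_loss, model, rng, eps=1e-6, n_per_param=3):
    """Central finite differences against the autodiff gradients."""
    model.zero_grad()
    build_loss().backward()
    for name, p in model.named_parameters():
        grad = p.grad
        assert grad is not None or not p.requires_grad, f"no grad for {name}"
        if grad is None:
            continue
        flat = p.data.ravel()
        for i in rng.choice(flat.size, size=min(n_per_param, flat.size),
                            replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            up = float(build_loss().data)
            flat[i] = orig - eps
            down = float(build_loss().data)
            flat[i] = orig
            numeric = (up - down) / (2 * eps)
            analytic = float(grad.ravel()[i])
            assert abs(numeric - analytic) < 1e-6 + 1e-4 * (abs(numeric) + abs(analytic)), \
                f"{name}[{i}]: numeric {numeric} vs analytic {analytic}"
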