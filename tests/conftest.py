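import pytest

from nsclc_cea import build_trace, evaluate_model, load_config


@pytest.fixture(scope="session")
def bundle():
    """The packaged base-case configuration."""
    return load_config()


@pytest.fixture(scope="session")
def strategies(bundle):
    combo, chemo = bundle.strategies()
    return {"combo": combo, "chemo": chemo}


@pytest.fixture(scope="session")
def traces(bundle):
    """Transition-engine traces for both arms at packaged defaults."""
    return {
        arm: build_trace(
            bundle.weibull[(arm, "PFS")],
            bundle.weibull[(arm, "OS")],
            bundle.settings,
            mode="transition",
            arm=arm,
        )
        for arm in ("combo", "chemo")
    }


@pytest.fixture(scope="session")
def base_result(bundle):
    return evaluate_model(bundle)
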