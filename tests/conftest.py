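from hypothesis import HealthCheck, settings

settings.register_profile(
    "molesim",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("molesim")
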