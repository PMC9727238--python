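import numpy as np
import pytest

from pitchchain.synth import PitchProfile, generate_trial, analytic_cases


@pytest.fixture(scope="session")
def clean_pitch():
    """Noise-free default pitch with its ground truth."""
    profile = PitchProfile(noise_sigma=0.0, ball_speed_noise_mph=0.0, seed=0)
    trial, truth = generate_trial(profile)
    return trial, truth


@pytest.fixture(scope="session")
def noisy_pitch():
    """Default pitch with 0.5 mm marker noise."""
    profile = PitchProfile(noise_sigma=0.0005, ball_speed_noise_mph=0.0, seed=1)
    trial, truth = generate_trial(profile)
    return trial, truth


@pytest.fixture(scope="session")
def oracle_cases():
    return {c.name: c for c in analytic_cases()}


def run_arm_dynamics(trial, truth=None):
    """frames, omegas, params, loads, powers for one preprocessed-clean trial."""
    import pitchchain as pc
    from pitchchain import dynamics

    frames = pc.build_segment_frames(trial)
    omegas = {s: pc.angular_velocity(frames[s]) for s in frames}
    hand_distal = trial.markers["MC3"].positions
    params = dynamics.zatsiorsky_params(
        trial.subject, dynamics.segment_lengths(frames, hand_distal)
    )
    loads = dynamics.inverse_dynamics_topdown(frames, omegas, params, hand_distal)
    powers = {
        "elbow": dynamics.joint_power(loads["elbow"], omegas["upper_arm"], omegas["forearm"]),
        "shoulder": dynamics.joint_power(loads["shoulder"], omegas["trunk"], omegas["upper_arm"]),
        "wrist": dynamics.joint_power(loads["wrist"], omegas["forearm"], omegas["hand"]),
    }
    return frames, omegas, params, loads, powers
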