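import pytest

from ethoindex import DurationProfile, Encounter, PairingGroup, SecondSeries


@pytest.fixture
def mixed_profile() -> DurationProfile:
    """100 s antennation, 60 s ignoring, 10 s fighting — the hand-trace case."""
    return DurationProfile({-2: 100, 0: 60, 3: 10})


def make_encounter(
    profiles,
    encounter_id="e1",
    pairing_id="p1",
    replicate=1,
    encounter_type="internest",
    day=None,
):
    """Build an encounter from 1-2 duration profiles (block-ordered series)."""
    series = tuple(
        DurationProfile(p).to_series(worker=f"w{i + 1}")
        for i, p in enumerate(profiles)
    )
    return Encounter(
        encounter_id=encounter_id,
        pairing_id=pairing_id,
        replicate=replicate,
        encounter_type=encounter_type,
        day=day,
        series=series,
    )


def make_group(profile_lists, pairing_id="p1", encounter_type="internest"):
    """Build a pairing group; one entry of profile_lists per replicate."""
    encounters = tuple(
        make_encounter(
            profiles,
            encounter_id=f"{pairing_id}e{r}",
            pairing_id=pairing_id,
            replicate=r,
            encounter_type=encounter_type,
        )
        for r, profiles in enumerate(profile_lists, start=1)
    )
    return PairingGroup(pairing_id=pairing_id, encounters=encounters)
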