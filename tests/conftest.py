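import pytest

from flpgraze.core_io import GrazingExperiment, UptakeTimepoint, load_mcr_dataset


@pytest.fixture(scope="session")
def mcr():
    """Packaged Mid-Cayman Rise dataset: (experiments, reference frame)."""
    return load_mcr_dataset()


def make_experiment(points, *, approach="ambient", habitat="vent",
                    vent_field="VonDamm", prok=7.11e4, euk=370.0,
                    flp=1000.0, grazers=100, experiment_id="exp1"):
    """Build an experiment whose pooled mean FLP per grazer hits ``points``.

    ``points`` is a list of (time_min, mean_flp_per_grazer); one replicate
    of ``grazers`` grazers per timepoint, total FLP = mean * grazers (must
    come out integral).  The last timepoint is marked final.
    """
    timepoints = []
    t_final = max(t for t, _ in points)
    for t, mean in points:
        total = mean * grazers
        assert abs(total - round(total)) < 1e-9, "mean*grazers must be integral"
        timepoints.append(UptakeTimepoint(
            time_min=float(t), replicate_id="r1",
            n_grazers_counted=grazers, total_flp_ingested=int(round(total)),
            is_final=t == t_final))
    return GrazingExperiment(
        experiment_id=experiment_id, vent_field=vent_field, site="test",
        habitat=habitat, approach=approach, temperature_c=50.0,
        euk_cells_ml=euk, prok_cells_ml=prok, flp_conc_t0=flp,
        timepoints=timepoints)


@pytest.fixture
def exp_factory():
    return make_experiment
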