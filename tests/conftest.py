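import numpy as np
import pytest

from wheatspad import synthetic
from wheatspad.bandstack import extract_plot
from wheatspad.calibration import apply_elm, fit_elm


@pytest.fixture(scope="session")
def design():
    return synthetic.ExperimentDesign(seed=42)


@pytest.fixture(scope="session")
def campaign(design):
    """One full synthetic campaign: ground truth + imagery, seed 42."""
    gt, images = synthetic.simulate_experiment(design, seed=42)
    return gt, images


@pytest.fixture(scope="session")
def heading_plots(campaign):
    """Calibrated reflectance plot images for the heading stage."""
    gt, images = campaign
    plots = []
    for row in gt[gt.stage == "heading"].itertuples(index=False):
        stack, region, panels = images[(row.plot_id, row.stage)]
        refl = apply_elm(stack, fit_elm(stack, panels))
        plots.append(extract_plot(refl, region))
    return plots


@pytest.fixture(scope="session")
def noise_free_plot():
    """A single rendered plot with all noise sources disabled."""
    params = synthetic.CanopyParams(noise=False, stripes=False)
    design = synthetic.ExperimentDesign(seed=0)
    gt = synthetic.simulate_spad(synthetic.generate_design(design),
                                 synthetic.SpadModelParams(), seed=0)
    row = gt.iloc[0]
    return synthetic.render_plot_image(row, design, params, seed=0)


def rng(seed=0):
    return np.random.default_rng(seed)
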