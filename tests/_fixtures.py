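"""Hand-built datasets shared between unit and acceptance tests."""

import numpy as np

from txclock import AgeAnnotation, CountMatrix


def linear_log_gene_dataset():
    """Age is an exact linear function of one gene's log1p count.

    Gene ``driver`` carries all the signal (age = 3 * ln(1 + count)); five
    other genes are pure seeded noise.  A near-unregularized Elastic Net
    should recover the relationship almost perfectly.
    """
    driver = np.array([2, 5, 10, 20, 40, 80, 150, 300, 600, 1200, 2400, 4800])
    ages = 3.0 * np.log1p(driver)
    rng = np.random.default_rng(1234)
    noise = rng.integers(0, 100, size=(5, driver.size))
    counts = np.vstack([driver, noise])
    gene_ids = ["driver"] + [f"noise{i}" for i in range(5)]
    sample_ids = [f"s{i:02d}" for i in range(driver.size)]
    cm = CountMatrix(gene_ids, sample_ids, counts)
    ann = AgeAnnotation(dict(zip(sample_ids, ages)))
    return cm, ann
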