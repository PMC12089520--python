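import numpy as np
from scipy.special import ndtr
from scipy.stats import binom, norm
from todo_design import DLMHyperparams, TrialData, get_tables, probit, QuadratureSettings

P0 = 0.2
hp = DLMHyperparams(theta=probit(P0), sigma1=50.0, tau=50.0)
tab = get_tables(hp, P0, 0.05)
s = tab.summary(TrialData(3, 10, 0, 0))
print("engine pr1:", s.pr_exceed[0], "mean1:", s.post_mean[0])

# very fine oracle
mu = np.linspace(-12, 12, 200001)
p = ndtr(mu)
w = norm.pdf(mu, hp.theta, hp.sigma1) * binom.pmf(3, 10, p)
z = np.trapezoid(w, mu)
print("oracle fine pr1:", np.trapezoid(w*(p>P0), mu)/z, "mean:", np.trapezoid(w*p, mu)/z)

# engine at fine resolution
fine = QuadratureSettings(mu_step=0.01, sigma_nodes=64)
tf = get_tables(hp, P0, 0.05, fine)
sf = tf.summary(TrialData(3, 10, 0, 0))
print("engine fine pr1:", sf.pr_exceed[0], "mean1:", sf.post_mean[0])
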