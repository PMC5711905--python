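# Reference relaxation-to-stationarity experiment: an ensemble of
# proportional-abundance diffusion trajectories started well away from the
# long-run mean, integrated until the terminal sample is stationary.
command: simulate
scheme: sde
m: 0.09
p: 0.0044
lam: 0.001585
z0: 0.2
t_end: 1000.0
dt: 0.01
n_traj: 225
level: 0.95
hist_bins: 30
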