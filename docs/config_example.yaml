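# Annotated pipeline configuration for `placemaps sweep|optimize --config ...`
# (also accepted by placemaps.pipeline.run_pipeline).

seed: 1               # master seed; every stage derives its own from it
n_cells: 8            # simulated place cells (trajectories are reused in
                      # cycles of up to 8, as in multi-session datasets)
duration_min: 16      # session duration in minutes (walks are clipped)
size_group: medium    # small | medium | large (2-SD radii 126/179/253 mm)
bias_mode: uniform    # uniform | goal | thigmotaxis trajectory sampling
overdispersion: false # add the 1.5 Hz firing-rate modulation

method: histogram     # histogram | ash | adaptive_smooth | adaptive_bin |
                      # ksde | tksde
bin_sizes: [10.0, 20.0, 40.0, 80.0, 160.0]   # mm
smoothings: [0.0, 20.0, 40.0, 80.0, 160.0]   # method-specific units:
                      # sigma mm (histogram), m (ash), alpha
                      # (adaptive_smooth), t s (adaptive_bin),
                      # bandwidth mm (ksde), spatial sigma mm (tksde)
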