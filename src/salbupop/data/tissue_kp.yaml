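# Tissue:plasma partition coefficients (Kp) for the 13 perfusion-limited
# tissues. The single bone value is applied to both marrow depots.
liver: 9.01
spleen: 6.70
muscle: 3.27
heart: 3.01
brain: 3.01
adipose: 0.55
lung: 7.83
kidney: 3.01
skin: 3.21
red_marrow: 2.27
yellow_marrow: 2.27
reproductive: 9.75
rest_of_body: 6.70
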