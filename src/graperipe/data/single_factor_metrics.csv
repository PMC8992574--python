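variety,metric,R,G,B,H,S,I
drunk_incense,r2,0.65,0.63,0.41,0.56,0.37,0.61
drunk_incense,mae,0.09,0.1,0.11,0.12,0.18,0.12
drunk_incense,rmse,0.12,0.13,0.24,0.14,0.26,0.13
drunk_incense,d,0.76,0.7,0.67,0.72,0.62,0.73
muscat_hamburg,r2,0.36,0.61,0.48,0.58,0.41,0.58
muscat_hamburg,mae,0.24,0.1,0.14,0.16,0.17,0.11
muscat_hamburg,rmse,0.29,0.12,0.13,0.13,0.25,0.16
muscat_hamburg,d,0.53,0.75,0.68,0.73,0.59,0.71
xiang_yue,r2,0.38,0.6,0.42,0.59,0.46,0.57
xiang_yue,mae,0.23,0.08,0.1,0.09,0.16,0.13
xiang_yue,rmse,0.27,0.11,0.23,0.12,0.11,0.12
xiang_yue,d,0.51,0.61,0.54,0.6,0.54,0.59
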