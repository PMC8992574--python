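variety,model,total,correct,overestimated,underestimated
muscat_hamburg,RG,75,61,7,6
drunk_incense,HI,75,57,8,10
xiang_yue,HI,75,66,5,4
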