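table,class_label,class_index,area_hm2,printed_proportion_pct
table2,insensitive,1,56722.69,27.65
table2,slightly sensitive,3,61215.37,29.84
table2,moderately sensitive,5,38218.58,18.63
table2,highly sensitive,7,28535.72,13.91
table2,extremely sensitive,9,20452.99,9.97
table3,moderately sensitive,5,76695.35,37.39
table3,highly sensitive,7,97184.32,47.37
table3,extremely sensitive,9,31265.67,15.24
table4,moderately sensitive,5,143929.76,70.16
table4,highly sensitive,7,17770.25,8.66
table4,extremely sensitive,9,43445.33,21.18
table6,slightly sensitive,3,60497.36,29.49
table6,moderately sensitive,5,53317.27,25.99
table6,highly sensitive,7,61789.78,30.12
table6,extremely sensitive,9,29540.93,14.40
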