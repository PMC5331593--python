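# Equivalent-sugar converting factors for recipe ingredients
# (fraction of the ingredient weight counted as free sugars).
# White sugar and honey are fixed anchors; syrup and fruit-juice-concentrate
# factors are configurable defaults.
white_sugar: 1.0
honey: 0.8
syrup: 0.8
fruit_juice_concentrate: 1.0
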