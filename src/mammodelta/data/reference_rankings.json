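{
 "t_test": [
  "Area",
  "Major Axis Length",
  "Minor Axis Length",
  "Convex Area",
  "Filled Area",
  "Equivalent Diameter",
  "Perimeter",
  "Energy 45 D2",
  "Energy 135 D2",
  "Energy Mean D2",
  "Energy 0 D3",
  "Energy 45 D3",
  "Energy 90 D3",
  "Energy 135 D3",
  "Energy Mean D3"
 ],
 "mrmr": [
  "Minor Axis Length",
  "Euler Number",
  "Solidity",
  "Contrast STD D1",
  "Energy STD D1",
  "Homogeneity STD D1",
  "Contrast STD D2",
  "Energy STD D2",
  "Homogeneity 45 D2",
  "Homogeneity STD D2",
  "Contrast 90 D3",
  "Contrast STD D3",
  "Correlation 45 D3",
  "Correlation 135 D3",
  "Correlation Mean D3",
  "Energy 45 D3",
  "Energy STD D3",
  "Homogeneity Mean D3",
  "Circularity",
  "Homogeneity 135 D3",
  "Compactness",
  "Homogeneity STD D3",
  "Smoothness",
  "Shape Ratio"
 ],
 "fi_et": [
  "Area",
  "Minor Axis Length",
  "Convex Area",
  "Filled Area",
  "Euler Number",
  "Equivalent Diameter",
  "Perimeter",
  "Mean Intensity",
  "Max Intensity",
  "STD",
  "Variance",
  "Energy STD D1",
  "Energy STD D2",
  "Energy 45 D3",
  "Energy 135 D3",
  "Energy STD D3",
  "Homogeneity 45 D3",
  "Circularity",
  "Homogeneity Mean D3",
  "Compactness",
  "Shape Ratio",
  "Smoothness",
  "Breast Density"
 ],
 "fi_rf": [
  "Area",
  "Minor Axis Length",
  "Euler Number",
  "Equivalent Diameter",
  "Solidity",
  "Perimeter",
  "Max Intensity",
  "STD",
  "Energy STD D1",
  "Homogeneity STD D1",
  "Energy STD D2",
  "Homogeneity STD D2",
  "Energy 45 D3",
  "Energy 135 D3",
  "Energy STD D3",
  "Homogeneity 135 D3",
  "Homogeneity STD D3",
  "Homogeneity 0 D3",
  "Circularity",
  "Shape Ratio"
 ],
 "fi_xgb": [
  "Area",
  "Minor Axis Length",
  "Euler Number",
  "Perimeter",
  "Contrast 45 D1",
  "Correlation STD D1",
  "Energy STD D1",
  "Homogeneity STD D1",
  "Contrast 135 D2",
  "Correlation 0 D2",
  "Homogeneity 45 D2",
  "Homogeneity 135 D2",
  "Homogeneity STD D2",
  "Correlation 135 D3",
  "Energy 90 D3",
  "Homogeneity 0 D3",
  "Homogeneity 135 D3",
  "Circularity",
  "Compactness",
  "Homogeneity STD D3"
 ],
 "select_k_best": [
  "Area",
  "Major Axis Length",
  "Minor Axis Length",
  "Convex Area",
  "Filled Area",
  "Equivalent Diameter",
  "Perimeter",
  "Energy 45 D2",
  "Energy 135 D2",
  "Energy Mean D2",
  "Energy 0 D3",
  "Energy 45 D3",
  "Energy 90 D3",
  "Energy 135 D3",
  "Energy Mean D3",
  "Homogeneity 135 D3"
 ],
 "sfs": [
  "Orientation",
  "Convex Area",
  "Euler Number",
  "Solidity",
  "Extent",
  "Mean Intensity",
  "Min Intensity",
  "Contrast 45 D2",
  "Correlation 90 D2",
  "Energy 45 D2",
  "Contrast 45 D3",
  "Contrast 135 D3",
  "Circularity",
  "Compactness",
  "Homogeneity 135 D3",
  "Homogeneity Mean D3"
 ],
 "sbs": [
  "Area",
  "Filled Area",
  "Euler Number",
  "Perimeter",
  "Shape Ratio"
 ]
}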