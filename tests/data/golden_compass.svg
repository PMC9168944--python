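<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="600" height="600" viewBox="0 0 600 600">
<g id="compass" data-respondent="r01" data-timepoint="12-month">
<path id="sector-life" d="M 300.000 60.000 A 240.000 240.000 0 0 1 487.640 150.362 L 345.033 264.087 A 57.600 57.600 0 0 0 300.000 242.400 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-life" d="M 300.000 242.400 A 57.600 57.600 0 0 1 345.033 264.087 L 322.517 282.043 A 28.800 28.800 0 0 0 300.000 271.200 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-life" x="410.206" y="71.154" font-size="13" font-family="sans-serif" text-anchor="middle">Life</text>
<path id="sector-cognition" d="M 487.640 150.362 A 240.000 240.000 0 0 1 533.983 353.405 L 356.156 312.817 A 57.600 57.600 0 0 0 345.033 264.087 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-cognition" d="M 345.033 264.087 A 57.600 57.600 0 0 1 356.156 312.817 L 328.078 306.409 A 28.800 28.800 0 0 0 322.517 282.043 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-cognition" x="547.632" y="243.480" font-size="13" font-family="sans-serif" text-anchor="middle">Cognition</text>
<path id="sector-emotion" d="M 533.983 353.405 A 240.000 240.000 0 0 1 404.132 516.233 L 324.992 351.896 A 57.600 57.600 0 0 0 356.156 312.817 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-emotion" d="M 356.156 312.817 A 57.600 57.600 0 0 1 324.992 351.896 L 312.496 325.948 A 28.800 28.800 0 0 0 328.078 306.409 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-emotion" x="498.585" y="458.366" font-size="13" font-family="sans-serif" text-anchor="middle">Emotion</text>
<path id="sector-fatigue" d="M 404.132 516.233 A 240.000 240.000 0 0 1 195.868 516.233 L 275.008 351.896 A 57.600 57.600 0 0 0 324.992 351.896 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-fatigue" d="M 324.992 351.896 A 57.600 57.600 0 0 1 275.008 351.896 L 287.504 325.948 A 28.800 28.800 0 0 0 312.496 325.948 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-fatigue" x="300.000" y="554.000" font-size="13" font-family="sans-serif" text-anchor="middle">Fatigue</text>
<path id="sector-sexuality_continence" d="M 195.868 516.233 A 240.000 240.000 0 0 1 66.017 353.405 L 243.844 312.817 A 57.600 57.600 0 0 0 275.008 351.896 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-sexuality_continence" d="M 275.008 351.896 A 57.600 57.600 0 0 1 243.844 312.817 L 271.922 306.409 A 28.800 28.800 0 0 0 287.504 325.948 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-sexuality_continence" x="101.415" y="458.366" font-size="13" font-family="sans-serif" text-anchor="middle">Sexuality and continence</text>
<path id="sector-sensory" d="M 66.017 353.405 A 240.000 240.000 0 0 1 112.360 150.362 L 254.967 264.087 A 57.600 57.600 0 0 0 243.844 312.817 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-sensory" d="M 243.844 312.817 A 57.600 57.600 0 0 1 254.967 264.087 L 277.483 282.043 A 28.800 28.800 0 0 0 271.922 306.409 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-sensory" x="52.368" y="243.480" font-size="13" font-family="sans-serif" text-anchor="middle">Sensory function</text>
<path id="sector-motor" d="M 112.360 150.362 A 240.000 240.000 0 0 1 300.000 60.000 L 300.000 242.400 A 57.600 57.600 0 0 0 254.967 264.087 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="2" data-score="100.000"/>
<path id="minband-motor" d="M 254.967 264.087 A 57.600 57.600 0 0 1 300.000 242.400 L 300.000 271.200 A 28.800 28.800 0 0 0 277.483 282.043 Z" fill="#2CA02C" stroke="#FFFFFF" stroke-width="1" data-score="100.000"/>
<text id="label-motor" x="189.794" y="71.154" font-size="13" font-family="sans-serif" text-anchor="middle">Motor function</text>
</g>
<g id="legend">
<rect id="legend-red" x="10.000" y="10.000" width="16" height="16" fill="#D62728"/>
<text x="32.000" y="23.000" font-size="12" font-family="sans-serif">red</text>
<rect id="legend-orange" x="10.000" y="32.000" width="16" height="16" fill="#FF7F0E"/>
<text x="32.000" y="45.000" font-size="12" font-family="sans-serif">orange</text>
<rect id="legend-green" x="10.000" y="54.000" width="16" height="16" fill="#2CA02C"/>
<text x="32.000" y="67.000" font-size="12" font-family="sans-serif">green</text>
<rect id="legend-missing" x="10.000" y="76.000" width="16" height="16" fill="#BFBFBF"/>
<text x="32.000" y="89.000" font-size="12" font-family="sans-serif">missing</text>
</g>
</svg>
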